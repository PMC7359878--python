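"""Forward model from spikes and membrane potential to GCaMP6f fluorescence.

The chain emulates what a two-photon microscope would report for each
neuron of a simulated network:

1. spike waveforms are painted back onto the reset-clamped membrane trace
   (integrate-and-fire models cut the action potential off at threshold);
2. an L-type high-voltage-activated calcium current
   ``I_Ca = g_Ca s(V) (V - E_Ca)`` with Boltzmann activation
   ``s(V) = 1 / (1 + exp(-(V - V_half)/rho))``;
3. intracellular calcium accumulating in proportion to the current and
   decaying back to baseline with tau_Ca:
   ``d[Ca]/dt = -k_Ca I_Ca - ([Ca] - Ca_basal)/tau_Ca``;
4. saturating Hill fluorescence of the GCaMP6f indicator:
   ``F = dF + K_F Ca^nH / (Ca^nH + k_d^nH)``.

Units: Vm in mV, I_Ca in uA/cm^2, Ca in nM, time in ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np

from .adex import AdexRun
from .containers import SignalTimeSeries

__all__ = [
    "CalciumParams",
    "CalciumTrace",
    "FluorescenceTrace",
    "reconstruct_spike_waveforms",
    "calcium_current",
    "integrate_calcium",
    "fluorescence",
    "population_fluorescence",
    "fluorescence_from_run",
]


@dataclass
class CalciumParams:
    """Constants of the calcium and indicator model (GCaMP6f defaults)."""

    E_Ca: float = 120.0      # reversal potential, mV
    g_Ca: float = 5.0        # maximal conductance, mS/cm^2
    V_half: float = -25.0    # Boltzmann half-activation, mV
    rho: float = 5.0         # Boltzmann slope, mV
    k_Ca: float = 0.002      # (nM/ms) per (uA/cm^2)
    tau_Ca: float = 760.0    # calcium decay, ms
    Ca_basal: float = 0.0    # basal concentration, nM
    dF: float = 0.0          # fluorescence offset
    K_F: float = 10.0        # fluorescence scale
    k_d: float = 375.0       # indicator dissociation constant, nM
    n_H: float = 2.3         # Hill coefficient
    spike_peak: float = 30.0  # reconstructed spike amplitude, mV
    spike_width: float = 1.0  # reconstructed spike width, ms

    def __post_init__(self) -> None:
        if self.tau_Ca <= 0 or self.k_d <= 0 or self.n_H <= 0 or self.rho <= 0:
            raise ValueError("tau_Ca, k_d, n_H and rho must be positive")
        if self.spike_width <= 0:
            raise ValueError("spike_width must be positive")


@dataclass
class CalciumTrace:
    """Intracellular calcium concentration (nM) over time."""

    ca: np.ndarray
    dt: float  # ms

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class FluorescenceTrace:
    """Indicator fluorescence (arbitrary units) over time."""

    f: np.ndarray
    dt: float  # ms

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def reconstruct_spike_waveforms(vm: np.ndarray, spike_times: np.ndarray, dt: float,
                                params: CalciumParams | None = None) -> np.ndarray:
    """Paint stereotyped spikes onto a reset-clamped membrane trace.

    Each spike overwrites ``spike_width`` ms of the trace (starting at the
    spike time) with a rectangular pulse of amplitude ``spike_peak``;
    everywhere else the trace is unchanged. The exact waveform barely
    matters downstream because the Boltzmann calcium activation saturates
    above ~0 mV.

    Parameters
    ----------
    vm : array, shape (..., T)
        Membrane trace(s), mV; last axis is time with step ``dt`` ms.
    spike_times : array
        Spike times in ms relative to the trace start.
    """
    params = params or CalciumParams()
    vm = np.asarray(vm, dtype=float)
    out = vm.copy()
    n = vm.shape[-1]
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    if spike_times.size and (spike_times.min() < 0
                             or spike_times.max() > (n - 1) * dt):
        raise ValueError("spike time outside the trace span")
    if spike_times.size > 1 and np.any(np.diff(spike_times) < params.spike_width):
        raise ValueError("spikes closer than spike_width; refractory contract violated")
    width = max(1, int(round(params.spike_width / dt)))
    for t in spike_times:
        k = int(round(t / dt))
        out[..., k:k + width] = params.spike_peak
    return out


def boltzmann_activation(vm: np.ndarray, params: CalciumParams | None = None) -> np.ndarray:
    """Steady-state voltage-dependent channel activation s(V) in (0, 1)."""
    params = params or CalciumParams()
    return 1.0 / (1.0 + np.exp(-(np.asarray(vm, dtype=float) - params.V_half) / params.rho))


def calcium_current(vm: np.ndarray, params: CalciumParams | None = None) -> np.ndarray:
    """L-type calcium current I_Ca = g_Ca s(V) (V - E_Ca), in uA/cm^2.

    Negative (inward) for V below the reversal potential.
    """
    params = params or CalciumParams()
    vm = np.asarray(vm, dtype=float)
    return params.g_Ca * boltzmann_activation(vm, params) * (vm - params.E_Ca)


def integrate_calcium(i_ca: np.ndarray, dt: float,
                      params: CalciumParams | None = None,
                      ca0: float | np.ndarray | None = None) -> CalciumTrace:
    """Forward-Euler integration of the calcium balance.

    d[Ca]/dt = -k_Ca I_Ca - ([Ca] - Ca_basal)/tau_Ca, starting from
    ``ca0`` (basal by default). Inward (negative) current raises calcium.
    Concentrations are clamped at zero (possible only with sustained
    outward current), with a warning.
    """
    params = params or CalciumParams()
    if dt <= 0:
        raise ValueError("dt must be positive")
    orig_1d = np.asarray(i_ca).ndim == 1
    i_ca = np.atleast_2d(np.asarray(i_ca, dtype=float))
    n_cells, n_t = i_ca.shape
    ca = np.empty((n_cells, n_t))
    state = np.full(n_cells, params.Ca_basal if ca0 is None else ca0, dtype=float)
    clamped = False
    decay = dt / params.tau_Ca
    for t in range(n_t):
        state = state + dt * (-params.k_Ca * i_ca[:, t]) \
            - decay * (state - params.Ca_basal)
        neg = state < 0
        if np.any(neg):
            state[neg] = 0.0
            clamped = True
        ca[:, t] = state
    if clamped:
        warn("calcium clamped at 0 (outward I_Ca drove it negative)", stacklevel=2)
    return CalciumTrace(ca=ca[0] if orig_1d else ca, dt=dt)


def fluorescence(ca: CalciumTrace | np.ndarray, params: CalciumParams | None = None,
                 dt: float | None = None, literal_hill: bool = False) -> FluorescenceTrace:
    """GCaMP6f fluorescence from calcium via the Hill saturation curve.

    F = dF + K_F Ca^nH / (Ca^nH + k_d^nH); exactly half-saturated at
    Ca = k_d. With ``literal_hill`` the denominator uses an unexponentiated
    k_d (a dimensionally inconsistent variant kept for comparison).
    """
    params = params or CalciumParams()
    if isinstance(ca, CalciumTrace):
        arr, dt = ca.ca, ca.dt
    else:
        arr = np.asarray(ca, dtype=float)
        if dt is None:
            raise ValueError("dt required when passing a bare array")
    if np.any(arr < 0):
        raise ValueError("calcium concentrations must be nonnegative")
    ca_pow = np.power(arr, params.n_H)
    kd = params.k_d if literal_hill else params.k_d ** params.n_H
    f = params.dF + params.K_F * ca_pow / (ca_pow + kd)
    return FluorescenceTrace(f=f, dt=dt)


def population_fluorescence(traces: list[FluorescenceTrace] | FluorescenceTrace,
                            populations: dict[str, np.ndarray] | None = None
                            ) -> dict[str, FluorescenceTrace]:
    """Arithmetic per-time-point mean fluorescence of labeled populations.

    ``traces`` is a list of single-cell traces (or one trace whose rows are
    cells); ``populations`` maps a label to the member cell indices
    (default: one population 'all' with every cell).
    """
    if isinstance(traces, FluorescenceTrace):
        stack = np.atleast_2d(traces.f)
        dt = traces.dt
    else:
        if not traces:
            raise ValueError("no traces given")
        lengths = {t.f.shape[-1] for t in traces}
        if len(lengths) != 1:
            raise ValueError("traces must have equal length")
        stack = np.vstack([np.atleast_2d(t.f) for t in traces])
        dt = traces[0].dt
    if populations is None:
        populations = {"all": np.arange(stack.shape[0])}
    out = {}
    for label, idx in populations.items():
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ValueError(f"population {label!r} is empty")
        out[label] = FluorescenceTrace(f=stack[idx].mean(axis=0), dt=dt)
    return out


def fluorescence_from_run(run: AdexRun, params: CalciumParams | None = None,
                          chunk_cells: int = 200) -> FluorescenceTrace:
    """Full spikes-to-fluorescence chain for every recorded neuron of a run.

    Applies spike reconstruction, the calcium current, calcium integration
    and the Hill fluorescence to each recorded membrane trace (processing
    cells in chunks to bound memory). Returns one trace whose rows are the
    recorded neurons, sampled at the run's recording step.
    """
    params = params or CalciumParams()
    if run.vm is None or run.recorded is None or run.dt_record is None:
        raise ValueError("run has no recorded membrane traces; pass record_vm")
    dt = run.dt_record
    n_cells = run.vm.shape[0]
    f = np.empty_like(run.vm, dtype=float)
    for lo in range(0, n_cells, chunk_cells):
        hi = min(lo + chunk_cells, n_cells)
        vm = run.vm[lo:hi].astype(float)
        t_max = (vm.shape[1] - 1) * dt
        for k in range(lo, hi):
            st = np.minimum(run.spikes[int(run.recorded[k])] * 1000.0, t_max)
            vm[k - lo] = reconstruct_spike_waveforms(vm[k - lo], st, dt, params)
        i_ca = calcium_current(vm, params)
        ca = integrate_calcium(i_ca, dt, params)
        f[lo:hi] = fluorescence(ca, params).f
    return FluorescenceTrace(f=f, dt=dt)


def fluorescence_signal(trace: FluorescenceTrace,
                        label: str = "fluorescence") -> SignalTimeSeries:
    """View a (population-mean) fluorescence trace as a SignalTimeSeries."""
    return SignalTimeSeries(data=np.atleast_2d(trace.f), fs=1000.0 / trace.dt,
                            labels=[label] if np.atleast_2d(trace.f).shape[0] == 1
                            else [f"{label}{i}" for i in range(np.atleast_2d(trace.f).shape[0])])
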