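"""RS/FS network of adaptive exponential integrate-and-fire (adex) neurons.

Two conductance-based populations — excitatory regular-spiking (RS) cells
with spike-frequency adaptation and inhibitory fast-spiking (FS) cells
without — generate anesthesia-like slow oscillations. The spike-triggered
adaptation increment ``b`` controls the rhythm: strong adaptation
(b = 60 pA, deep anesthesia) slows the Up-Down alternation, weak
adaptation (b = 20 pA, light anesthesia) speeds it up.

Membrane equation (voltages mV, currents pA, conductances nS, times ms):

    Cm dV/dt = Gl (El - V) + Gl DeltaV exp((V - Vthre)/DeltaV)
               + ge (Ee - V) + gi (Ei - V) - w + I_ext + sigma xi(t)

with synaptic conductances decaying exponentially (tau_syn) and
incremented by a quantum Q on each presynaptic spike, and adaptation

    dw/dt = (a (V - El) - w) / tau_w,     w -> w + b at each spike.

On spike (V >= Vthre) the membrane is reset to Vreset and clamped for a
refractory period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import signal as spsignal

from .containers import SignalTimeSeries

__all__ = [
    "AdexParams",
    "NetworkArchitecture",
    "AdexRun",
    "simulate_network",
    "population_rate",
    "oscillation_frequency",
]


@dataclass
class AdexParams:
    """Single-population adex neuron parameters.

    Units: conductances nS, capacitance pF, voltages mV, times ms,
    currents pA. ``sigma`` is the amplitude of the Gaussian white
    membrane-current noise in pA sqrt(ms) (per-step voltage kick
    ``sigma sqrt(dt) xi / Cm``). ``i_ext`` is a constant external drive.
    """

    Gl: float = 10.0
    Cm: float = 150.0
    El: float = -60.0
    Delta_V: float = 2.0
    V_thre: float = -50.0
    V_reset: float = -65.0
    T_refrac: float = 5.0
    tau_w: float = 500.0
    a: float = 4.0
    b: float = 60.0
    tau_syn: float = 5.0
    E_syn_exc: float = 0.0
    E_syn_inh: float = -80.0
    sigma: float = 0.0
    i_ext: float = 0.0

    def __post_init__(self) -> None:
        if self.Gl <= 0 or self.Cm <= 0:
            raise ValueError("Gl and Cm must be positive")
        if self.V_reset > self.V_thre:
            raise ValueError("V_reset must not exceed V_thre")
        if self.b < 0:
            raise ValueError("b must be nonnegative")
        if self.tau_w <= 0 or self.tau_syn <= 0:
            raise ValueError("tau_w and tau_syn must be positive")

    @classmethod
    def rs(cls, b: float = 60.0, **kw) -> "AdexParams":
        """Regular-spiking (excitatory, adapting) defaults; b = 60 pA models
        deep anesthesia, b = 20 pA light anesthesia."""
        kw.setdefault("sigma", DEFAULT_SIGMA)
        return cls(El=-60.0, Delta_V=2.0, a=4.0, b=b, **kw)

    @classmethod
    def fs(cls, **kw) -> "AdexParams":
        """Fast-spiking (inhibitory, non-adapting) defaults."""
        kw.setdefault("a", 0.0)
        kw.setdefault("b", 0.0)
        kw.setdefault("sigma", DEFAULT_SIGMA)
        return cls(El=-65.0, Delta_V=0.5, **kw)


# sigma, Q_exc and Q_inh are the calibration knobs that place the
# deep-anesthesia (b=60 pA) rhythm near 2.1 Hz with the default
# architecture; values frozen after a one-off calibration sweep
# (see docs/methods.md).
DEFAULT_SIGMA = 230.0   # pA sqrt(ms)
DEFAULT_Q_EXC = 1.5     # nS
DEFAULT_Q_INH = 10.0    # nS


@dataclass
class NetworkArchitecture:
    """Random network layout: sizes, wiring probability, synaptic quanta."""

    n_exc: int = 1600
    n_inh: int = 400
    p_connect: float = 0.02
    q_exc: float = DEFAULT_Q_EXC
    q_inh: float = DEFAULT_Q_INH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exc < 1 or self.n_inh < 1:
            raise ValueError("populations must have at least one neuron")
        if not 0 < self.p_connect <= 1:
            raise ValueError("p_connect must be in (0, 1]")

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh


@dataclass
class AdexRun:
    """Result of a network simulation.

    ``spikes`` holds one sorted spike-time array (seconds) per neuron;
    neurons ``0..n_exc-1`` are excitatory. ``vm``/``w`` are membrane and
    adaptation traces (mV / pA) for the recorded subset, sampled every
    ``dt_record`` ms.
    """

    spikes: list[np.ndarray]
    n_exc: int
    n_inh: int
    dt: float                   # integration step, ms
    duration: float             # s
    vm: np.ndarray | None = None        # (n_recorded, T)
    w: np.ndarray | None = None
    recorded: np.ndarray | None = None  # neuron indices of vm rows
    dt_record: float | None = None      # ms

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh

    def spike_counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.spikes])

    def spike_array(self) -> tuple[np.ndarray, np.ndarray]:
        """All spikes as (neuron_id, time_s) arrays sorted by time."""
        if not self.spikes:
            return np.empty(0, dtype=int), np.empty(0)
        ids = np.concatenate([np.full(len(s), i, dtype=int)
                              for i, s in enumerate(self.spikes)])
        times = np.concatenate(self.spikes)
        order = np.argsort(times, kind="stable")
        return ids[order], times[order]


@njit(cache=True)
def _adex_chunk(n, n_exc, t0, chunk_steps, dt,
                el, dv, a_arr, b_arr, tau_w, gl, cm, vthre, vreset,
                refrac_steps, tau_syn, e_exc, e_inh, sigma, i_ext,
                tgt_indptr, tgt_indices, q_exc, q_inh,
                noise, literal_adaptation,
                v, w, ge, gi, refrac,
                rec_idx, rec_every, vm_out, w_out,
                spike_id_out, spike_step_out, n_spikes):
    """Advance the network by `chunk_steps` steps starting at global step t0.

    State arrays (v, w, ge, gi, refrac) are updated in place; spikes are
    appended starting at index n_spikes. Returns the new spike count.
    """
    syn_decay = np.exp(-dt / tau_syn)
    noise_amp = sigma * np.sqrt(dt) / cm
    for tt in range(chunk_steps):
        t = t0 + tt
        if rec_idx.shape[0] > 0 and t % rec_every == 0:
            col = t // rec_every
            for k in range(rec_idx.shape[0]):
                vm_out[k, col] = v[rec_idx[k]]
                w_out[k, col] = w[rec_idx[k]]
        for i in range(n):
            # adaptation evolves also during the refractory clamp
            if literal_adaptation:
                dw = (-(gl / cm) * w[i] + a_arr[i] * (v[i] - el[i])) * dt
            else:
                dw = (a_arr[i] * (v[i] - el[i]) - w[i]) * dt / tau_w
            if refrac[i] > 0:
                refrac[i] -= 1
                v[i] = vreset
                w[i] += dw
                continue
            arg = (v[i] - vthre) / dv[i]
            if arg > 16.0:
                arg = 16.0  # overflow guard; this neuron spikes this step anyway
            exp_term = gl * dv[i] * np.exp(arg) if arg > -30.0 else 0.0
            i_total = (gl * (el[i] - v[i]) + exp_term
                       + ge[i] * (e_exc - v[i]) + gi[i] * (e_inh - v[i])
                       - w[i] + i_ext[i])
            v[i] += dt * i_total / cm + noise_amp * noise[tt, i]
            w[i] += dw
        # threshold crossings -> record, reset, clamp, adapt, propagate
        for i in range(n):
            if refrac[i] == 0 and v[i] >= vthre:
                spike_id_out[n_spikes] = i
                spike_step_out[n_spikes] = t
                n_spikes += 1
                v[i] = vreset
                refrac[i] = refrac_steps
                w[i] += b_arr[i]
                if i < n_exc:
                    for p in range(tgt_indptr[i], tgt_indptr[i + 1]):
                        ge[tgt_indices[p]] += q_exc
                else:
                    for p in range(tgt_indptr[i], tgt_indptr[i + 1]):
                        gi[tgt_indices[p]] += q_inh
        for i in range(n):
            ge[i] *= syn_decay
            gi[i] *= syn_decay
    return n_spikes


def _build_connectivity(arch: NetworkArchitecture) -> tuple[np.ndarray, np.ndarray]:
    """Random directed wiring (no autapses) as presyn->targets CSR arrays."""
    rng = np.random.default_rng(arch.seed)
    n = arch.n_total
    indptr = np.zeros(n + 1, dtype=np.int64)
    targets = []
    for j in range(n):
        mask = rng.random(n) < arch.p_connect
        mask[j] = False
        tgt = np.flatnonzero(mask)
        targets.append(tgt)
        indptr[j + 1] = indptr[j] + tgt.size
    indices = np.concatenate(targets).astype(np.int64)
    return indptr, indices


def simulate_network(
    arch: NetworkArchitecture,
    params_exc: AdexParams,
    params_inh: AdexParams,
    duration: float,
    seed: int = 0,
    dt: float = 0.1,
    record_vm: str | np.ndarray | None = None,
    record_decimate: int = 10,
    literal_adaptation: bool = False,
    v0: np.ndarray | float | None = None,
) -> AdexRun:
    """Simulate the RS/FS adex network.

    Parameters
    ----------
    duration : float
        Simulated time in seconds (>= 1 s).
    seed : int
        Seed for membrane noise and initial conditions (wiring uses
        ``arch.seed``); identical inputs give identical spikes and traces.
    dt : float
        Forward-Euler step in ms; must resolve the exponential upswing of
        the steepest population (rejected when dt > Delta_V/2 in ms-mV
        scale); 0.1 ms is safe for the default parameters.
    record_vm : None | 'exc' | 'inh' | 'all' | array of neuron indices
        Which membrane/adaptation traces to keep, decimated by
        ``record_decimate`` (1 kHz sampling at the default dt=0.1 ms).
    literal_adaptation : bool
        Use the fast-decay adaptation variant (membrane time constant
        Cm/Gl = 15 ms, a(V-El) coupling not normalized by tau_w) instead
        of the standard slow form with tau_w = 500 ms.
    v0 : float or array, optional
        Initial membrane potentials (default: uniform in El +- 2 mV).
    """
    if duration < 1.0:
        raise ValueError("duration must be at least 1 s")
    if dt > 0.5 * min(params_exc.Delta_V, params_inh.Delta_V):
        raise ValueError(
            f"dt={dt} ms too large for the exponential term at Delta_V="
            f"{min(params_exc.Delta_V, params_inh.Delta_V)} mV; use a smaller step"
        )
    for name in ("Gl", "Cm", "V_thre", "V_reset", "T_refrac", "tau_w",
                 "tau_syn", "E_syn_exc", "E_syn_inh", "sigma"):
        if getattr(params_exc, name) != getattr(params_inh, name):
            raise ValueError(f"populations must share {name} in this implementation")
    n_exc, n_inh = arch.n_exc, arch.n_inh
    n = n_exc + n_inh
    n_steps = int(round(duration * 1000.0 / dt))
    indptr, indices = _build_connectivity(arch)

    el = np.r_[np.full(n_exc, params_exc.El), np.full(n_inh, params_inh.El)]
    dv = np.r_[np.full(n_exc, params_exc.Delta_V), np.full(n_inh, params_inh.Delta_V)]
    a_arr = np.r_[np.full(n_exc, params_exc.a), np.full(n_inh, params_inh.a)]
    b_arr = np.r_[np.full(n_exc, params_exc.b), np.full(n_inh, params_inh.b)]
    i_ext = np.r_[np.full(n_exc, params_exc.i_ext), np.full(n_inh, params_inh.i_ext)]
    p = params_exc

    rng = np.random.default_rng(seed)
    drawn_v0 = el + rng.uniform(-2.0, 2.0, size=n)
    if v0 is None:
        v = drawn_v0
    else:
        v = np.broadcast_to(np.asarray(v0, dtype=float), (n,)).copy()
    w = np.zeros(n)
    ge = np.zeros(n)
    gi = np.zeros(n)
    refrac = np.zeros(n, dtype=np.int64)
    sigma = p.sigma

    if record_vm is None:
        rec_idx = np.empty(0, dtype=np.int64)
    elif isinstance(record_vm, str):
        rec_idx = {"exc": np.arange(n_exc), "inh": np.arange(n_exc, n),
                   "all": np.arange(n)}[record_vm].astype(np.int64)
    else:
        rec_idx = np.asarray(record_vm, dtype=np.int64)
    n_rec_cols = (n_steps + record_decimate - 1) // record_decimate
    vm_out = np.empty((rec_idx.size, n_rec_cols), dtype=np.float32)
    w_out = np.empty((rec_idx.size, n_rec_cols), dtype=np.float32)

    # refractory period bounds the rate, so this capacity cannot overflow
    refrac_steps = int(round(p.T_refrac / dt))
    cap = n * (n_steps // max(refrac_steps, 1) + 2)
    spike_id = np.empty(cap, dtype=np.int64)
    spike_step = np.empty(cap, dtype=np.int64)
    n_spikes = 0

    chunk = 10_000  # noise is generated per chunk to bound memory
    for t0 in range(0, n_steps, chunk):
        cs = min(chunk, n_steps - t0)
        noise = rng.standard_normal((cs, n)) if sigma > 0 else np.zeros((cs, n))
        n_spikes = _adex_chunk(
            n, n_exc, t0, cs, dt,
            el, dv, a_arr, b_arr, p.tau_w, p.Gl, p.Cm, p.V_thre, p.V_reset,
            refrac_steps, p.tau_syn, p.E_syn_exc, p.E_syn_inh,
            sigma, i_ext,
            indptr, indices, arch.q_exc, arch.q_inh,
            noise, literal_adaptation,
            v, w, ge, gi, refrac,
            rec_idx, record_decimate, vm_out, w_out,
            spike_id, spike_step, n_spikes,
        )

    spike_id = spike_id[:n_spikes]
    spike_times = spike_step[:n_spikes] * (dt / 1000.0)
    order = np.argsort(spike_id, kind="stable")  # stable keeps time order
    sorted_times = spike_times[order]
    bounds = np.searchsorted(spike_id[order], np.arange(n + 1))
    spikes = [sorted_times[bounds[i]:bounds[i + 1]] for i in range(n)]
    return AdexRun(
        spikes=spikes, n_exc=n_exc, n_inh=n_inh, dt=dt, duration=duration,
        vm=vm_out if rec_idx.size else None,
        w=w_out if rec_idx.size else None,
        recorded=rec_idx if rec_idx.size else None,
        dt_record=dt * record_decimate if rec_idx.size else None,
    )


def population_rate(run: AdexRun, bin_ms: float = 1.0,
                    population: str = "all") -> SignalTimeSeries:
    """Instantaneous population firing rate in Hz (spike counts per bin,
    normalized by bin width and population size)."""
    if bin_ms <= 0:
        raise ValueError("bin must be positive")
    if population == "exc":
        lo, hi = 0, run.n_exc
    elif population == "inh":
        lo, hi = run.n_exc, run.n_total
    elif population == "all":
        lo, hi = 0, run.n_total
    else:
        raise ValueError(f"unknown population {population!r}")
    n_pop = hi - lo
    if n_pop == 0:
        raise ValueError("empty population")
    times = np.concatenate(run.spikes[lo:hi]) if hi > lo else np.empty(0)
    n_bins = int(round(run.duration * 1000.0 / bin_ms))
    edges = np.arange(n_bins + 1) * (bin_ms / 1000.0)
    counts, _ = np.histogram(times, bins=edges)
    rate = counts / (bin_ms / 1000.0) / n_pop
    return SignalTimeSeries(data=rate[None, :], fs=1000.0 / bin_ms,
                            labels=[population])


def oscillation_frequency(sig: SignalTimeSeries, band: tuple[float, float] = (0.5, 10.0),
                          nperseg_seconds: float = 10.0,
                          peak_factor: float = 4.0) -> float:
    """Dominant oscillation frequency from the Welch spectrum peak in a band.

    Returns NaN when no clear peak exists (in-band maximum below
    ``peak_factor`` times the in-band median power). The peak location is
    refined by quadratic interpolation around the maximum bin.
    """
    x = sig.data[0] if sig.data.shape[0] == 1 else sig.data.mean(axis=0)
    f_lo, f_hi = band
    if sig.n_samples / sig.fs < 10.0 / f_lo:
        raise ValueError("signal too short: need >= 10 cycles of the band's lower edge")
    nperseg = min(sig.n_samples, int(round(nperseg_seconds * sig.fs)))
    freqs, power = spsignal.welch(x - x.mean(), fs=sig.fs, nperseg=nperseg)
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    if not np.any(in_band):
        raise ValueError("band contains no spectral bins")
    pb = power[in_band]
    fb = freqs[in_band]
    k = int(np.argmax(pb))
    if np.median(pb) <= 0 or pb[k] < peak_factor * np.median(pb):
        return float("nan")
    # quadratic refinement on log power where neighbors exist
    if 0 < k < pb.size - 1 and pb[k - 1] > 0 and pb[k + 1] > 0:
        y0, y1, y2 = np.log(pb[k - 1]), np.log(pb[k]), np.log(pb[k + 1])
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
            return float(fb[k] + shift * (fb[1] - fb[0]))
    return float(fb[k])
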