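"""Phase-coherence functional connectivity and the lesion-parameter grid fit.

The FC pipeline mirrors how wide-field calcium recordings are analyzed:
band-pass to the upper delta band (2.5-5 Hz by default elsewhere), extract
analytic phases with the Hilbert transform, and compute phase locking
values

    PLV_ij = | (1/M) sum_m exp(i (theta_i(m) - theta_j(m))) |,

with a surrogate ensemble (spectrum-preserving, cross-channel-phase
destroying) providing the significance floor. FC changes of a condition
versus a reference are compared with model FC changes over a grid of
stroke-damage and rebound-rewiring parameters; the fit metric is the
Pearson correlation of the strictly-upper-triangle change vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

from .connectome import Connectome, LesionSpec, apply_rebound
from .containers import SignalTimeSeries
from .kuramoto import (
    KuramotoParams,
    PhaseTimeSeries,
    _batch_stream,
    simulate_phase_locking,
)

__all__ = [
    "FCMatrix",
    "FCChange",
    "FitResult",
    "bandpass_filter",
    "analytic_phase",
    "plv_matrix",
    "surrogate_significance",
    "fc_change",
    "fc_from_signals",
    "fit_parameter_grid",
    "upper_triangle",
]


@dataclass
class FCMatrix:
    """Symmetric phase-locking-value matrix, entries in [0, 1], unit diagonal."""

    plv: np.ndarray
    labels: list[str] = field(default_factory=list)
    band: tuple[float, float] | None = None
    condition: str = "model"

    def __post_init__(self) -> None:
        self.plv = np.asarray(self.plv, dtype=float)
        n = self.plv.shape[0]
        if self.plv.ndim != 2 or self.plv.shape[1] != n:
            raise ValueError("PLV matrix must be square")
        if np.isnan(self.plv).any():
            raise ValueError("PLV matrix contains NaN")
        if not np.allclose(self.plv, self.plv.T, atol=1e-12):
            raise ValueError("PLV matrix must be symmetric")
        if self.plv.min() < -1e-12 or self.plv.max() > 1 + 1e-9:
            raise ValueError("PLV entries must lie in [0, 1]")
        if not self.labels:
            self.labels = [f"r{i:02d}" for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("labels must match matrix dimension")

    @property
    def n_regions(self) -> int:
        return self.plv.shape[0]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.plv, index=self.labels, columns=self.labels).to_csv(path)


@dataclass
class FCChange:
    """Change of FC versus a reference condition (symmetric, zero diagonal)."""

    delta: np.ndarray
    labels: list[str] = field(default_factory=list)
    mode: str = "difference"

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        n = self.delta.shape[0]
        if self.delta.ndim != 2 or self.delta.shape[1] != n:
            raise ValueError("change matrix must be square")
        if not np.allclose(self.delta, self.delta.T, atol=1e-9, equal_nan=True):
            raise ValueError("change matrix must be symmetric")
        if self.mode not in ("difference", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.labels:
            self.labels = [f"r{i:02d}" for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("labels must match matrix dimension")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.delta, index=self.labels, columns=self.labels).to_csv(path)


@dataclass
class FitResult:
    """Grid of model-vs-data FC-change correlations over (s, r)."""

    s_grid: np.ndarray        # retain fractions
    r_grid: np.ndarray        # rebound multiples
    values: np.ndarray        # (len(s_grid), len(r_grid)) Pearson correlations
    best_s: float
    best_r: float
    best_value: float

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values,
                     index=[f"s={s:g}" for s in self.s_grid],
                     columns=[f"r={r:g}" for r in self.r_grid]).to_csv(path)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"best_s": self.best_s, "best_r": self.best_r,
             "best_value": self.best_value}, indent=1))


def bandpass_filter(ts: SignalTimeSeries, f_lo: float, f_hi: float) -> SignalTimeSeries:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward)."""
    nyq = ts.fs / 2.0
    if not 0 < f_lo < f_hi:
        raise ValueError("need 0 < f_lo < f_hi")
    if f_hi >= nyq:
        raise ValueError(f"f_hi={f_hi} Hz at or above Nyquist {nyq} Hz")
    sos = signal.butter(4, [f_lo, f_hi], btype="bandpass", fs=ts.fs, output="sos")
    out = signal.sosfiltfilt(sos, ts.data, axis=1)
    return SignalTimeSeries(data=out, fs=ts.fs, labels=list(ts.labels))


def analytic_phase(ts: SignalTimeSeries) -> PhaseTimeSeries:
    """Instantaneous phase of each channel via the Hilbert transform.

    The input should already be band-limited for the phase to be
    physically meaningful.
    """
    if ts.n_samples < 64:
        raise ValueError("need at least 64 samples for a stable analytic signal")
    if np.any(ts.data.std(axis=1) == 0):
        i = int(np.flatnonzero(ts.data.std(axis=1) == 0)[0])
        raise ValueError(f"channel {ts.labels[i]!r} is constant; phase undefined")
    analytic = signal.hilbert(ts.data, axis=1)
    return PhaseTimeSeries(phases=np.angle(analytic), fs=ts.fs, labels=list(ts.labels))


def plv_matrix(phases: PhaseTimeSeries, band: tuple[float, float] | None = None,
               condition: str = "model") -> FCMatrix:
    """Pairwise phase locking values over all samples."""
    theta = phases.phases
    if theta.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    if np.isnan(theta).any():
        raise ValueError("phases contain NaN")
    z = np.exp(1j * theta)
    m = theta.shape[1]
    plv = np.abs(z @ z.conj().T) / m
    np.fill_diagonal(plv, 1.0)
    plv = np.clip((plv + plv.T) / 2.0, 0.0, 1.0)
    return FCMatrix(plv=plv, labels=list(phases.labels), band=band, condition=condition)


def _phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fourier-phase-randomized surrogate of a 1-D signal (spectrum preserved)."""
    n = x.shape[-1]
    spec = np.fft.rfft(x)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.shape[-1])
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0  # Nyquist bin stays real
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n)


def surrogate_significance(ts: SignalTimeSeries, n_surrogates: int = 100,
                           quantile: float = 0.95, seed: int = 0) -> FCMatrix:
    """Per-pair PLV significance threshold from phase-randomized surrogates.

    Each surrogate preserves every channel's power spectrum but draws
    independent Fourier phases per channel, destroying cross-channel phase
    relations; the threshold is the requested quantile of the surrogate
    PLV distribution for each pair.
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = ts.n_channels
    plvs = np.empty((n_surrogates, n, n))
    for k in range(n_surrogates):
        surr = np.stack([_phase_randomize(ts.data[i], rng) for i in range(n)])
        ph = analytic_phase(SignalTimeSeries(surr, ts.fs, list(ts.labels)))
        plvs[k] = plv_matrix(ph).plv
    thr = np.quantile(plvs, quantile, axis=0)
    np.fill_diagonal(thr, 1.0)
    thr = np.clip((thr + thr.T) / 2.0, 0.0, 1.0)
    return FCMatrix(plv=thr, labels=list(ts.labels), condition="surrogate-threshold")


def fc_change(fc_cond: FCMatrix, fc_ref: FCMatrix, mode: str = "difference") -> FCChange:
    """FC change of a condition versus a reference (difference or relative)."""
    if fc_cond.labels != fc_ref.labels:
        raise ValueError("condition and reference FC labels differ")
    if mode == "difference":
        delta = fc_cond.plv - fc_ref.plv
    elif mode == "relative":
        if np.any(fc_ref.plv == 0):
            raise ValueError("relative change undefined: reference PLV has zero entries")
        delta = (fc_cond.plv - fc_ref.plv) / fc_ref.plv
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(delta, 0.0)
    return FCChange(delta=delta, labels=list(fc_cond.labels), mode=mode)


def fc_from_signals(ts: SignalTimeSeries, band: tuple[float, float],
                    condition: str = "data") -> FCMatrix:
    """Band-pass -> analytic phase -> PLV, the standard empirical pipeline."""
    filtered = bandpass_filter(ts, band[0], band[1])
    return plv_matrix(analytic_phase(filtered), band=band, condition=condition)


def upper_triangle(matrix: np.ndarray, idx: np.ndarray | None = None) -> np.ndarray:
    """Strictly-upper-triangle entries (optionally of a region subset) as a vector."""
    m = np.asarray(matrix)
    if idx is not None:
        m = m[np.ix_(idx, idx)]
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _subset_indices(conn: Connectome, labels: list[str]) -> np.ndarray:
    return np.array([conn.region_index(l) for l in labels])


def fit_parameter_grid(
    data_change: FCChange,
    healthy_conn: Connectome,
    kp: KuramotoParams,
    s_grid,
    r_grid,
    seeds: list[int] | int = 10,
    mode: str = "difference",
    rebound_mode: str = "redistribute",
    acc_every: int = 5,
) -> FitResult:
    """Fit stroke-damage and rebound parameters to an observed FC change.

    For every (s, r) on the grid the healthy connectome is lesioned
    (retain fraction s) and rewired (rebound r), healthy and lesioned
    network models are simulated with paired seeds, and the seed-averaged
    model FC change on the data's region subset is correlated (Pearson,
    strictly-upper triangles) with the observed change. Ties in the argmax
    are broken toward smaller damage (larger s), then smaller r.

    ``seeds`` may be an explicit list or a count (seeds ``0..n-1``).
    """
    s_grid = np.atleast_1d(np.asarray(s_grid, dtype=float))
    r_grid = np.atleast_1d(np.asarray(r_grid, dtype=float))
    if s_grid.size == 0 or r_grid.size == 0:
        raise ValueError("parameter grids must be nonempty")
    if isinstance(seeds, (int, np.integer)):
        seeds = list(range(int(seeds)))
    if healthy_conn.stroke_region is None:
        raise ValueError("healthy connectome has no stroke region designated")
    if len(data_change.labels) < 3:
        raise ValueError("need at least 3 analysis regions for a meaningful correlation")
    idx = _subset_indices(healthy_conn, data_change.labels)
    data_vec = upper_triangle(data_change.delta)
    if np.std(data_vec) == 0:
        raise ValueError("observed FC change has zero variance; correlation undefined")

    # the paired-seed stream is identical for every connectome: draw it once
    stream = _batch_stream(kp, healthy_conn.n_regions, seeds)
    plv_healthy = simulate_phase_locking(healthy_conn, kp, seeds,
                                         acc_every=acc_every, _stream=stream)
    values = np.empty((s_grid.size, r_grid.size))
    for a, s in enumerate(s_grid):
        for b, r in enumerate(r_grid):
            spec = LesionSpec(stroke_region=healthy_conn.stroke_region,
                              retain_fraction=float(s), rebound=float(r))
            lesioned = apply_rebound(healthy_conn, spec, mode=rebound_mode)
            plv_lesioned = simulate_phase_locking(lesioned, kp, seeds,
                                                  acc_every=acc_every,
                                                  _stream=stream)
            if mode == "difference":
                change = plv_lesioned - plv_healthy
            elif mode == "relative":
                if np.any(plv_healthy == 0):
                    raise ValueError("relative change undefined: zero healthy PLV")
                change = (plv_lesioned - plv_healthy) / plv_healthy
            else:
                raise ValueError(f"unknown mode {mode!r}")
            mean_change = change.mean(axis=0)
            model_vec = upper_triangle(mean_change, idx)
            if np.std(model_vec) == 0:
                # a lesion with no effect (e.g. s=1) predicts a constant
                # change; it carries no correlation evidence
                values[a, b] = 0.0
            else:
                values[a, b] = stats.pearsonr(model_vec, data_vec).statistic

    # argmax, ties toward larger s (less damage) then smaller r
    best_value = -np.inf
    best_s = best_r = 0.0
    for a in np.argsort(-s_grid, kind="stable"):
        for b in np.argsort(r_grid, kind="stable"):
            if values[a, b] > best_value:
                best_value = values[a, b]
                best_s, best_r = float(s_grid[a]), float(r_grid[b])
    return FitResult(s_grid=s_grid, r_grid=r_grid, values=values,
                     best_s=best_s, best_r=best_r, best_value=best_value)
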