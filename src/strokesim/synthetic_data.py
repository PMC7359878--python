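"""Synthetic inputs for every pipeline stage: ground-truth lesion
experiments, calcium-like region signals, and Poisson spike trains.

Nothing here requires external data. Every generator is a pure function of
its parameters and seed, and ground-truth experiments carry a manifest
from which they can be regenerated bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as spsignal

from .connectome import Connectome, LesionSpec, apply_rebound, generate_synthetic_connectome
from .containers import SignalTimeSeries
from .fc import FCChange
from .kuramoto import KuramotoParams, simulate_phases, simulate_phase_locking

__all__ = [
    "GroundTruthExperiment",
    "generate_ground_truth_experiment",
    "generate_calcium_like_signals",
    "generate_poisson_spikes",
]


@dataclass
class GroundTruthExperiment:
    """A simulated stroke/rehab study with known structural parameters.

    ``data_change_stroke``/``data_change_rehab`` play the role of the
    empirical FC-change matrices: they are produced by the model itself at
    known lesion parameters (plus optional observation noise), restricted
    to an analysis subset of regions outside the stroke core, so parameter
    recovery can be scored against the truth.
    """

    healthy_conn: Connectome
    s_true: float
    r_true: float
    kp: KuramotoParams
    seeds: list[int]
    data_change_stroke: FCChange
    data_change_rehab: FCChange | None
    region_subset: list[str]
    manifest: dict = field(default_factory=dict)


def _observe_plv(plv: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add truncated-Gaussian observation noise to a PLV matrix."""
    if sigma == 0:
        return plv
    n = plv.shape[0]
    noise = rng.normal(0.0, sigma, size=(n, n))
    noise = np.triu(noise, 1)
    noisy = np.clip(plv + noise + noise.T, 0.0, 1.0)
    np.fill_diagonal(noisy, 1.0)
    return noisy


def generate_ground_truth_experiment(
    n_regions: int = 18,
    s_true: float = 0.3,
    r_true: float = 1.0,
    kp: KuramotoParams | None = None,
    seeds: list[int] | int = 10,
    s_rehab: float | None = None,
    r_rehab: float | None = None,
    obs_noise: float = 0.0,
    noise_seed: int = 12345,
    conn_seed: int = 1,
    density: float = 0.3,
    n_subset: int = 12,
    acc_every: int = 5,
) -> GroundTruthExperiment:
    """Simulate a stroke (and rehab) study with known lesion parameters.

    Healthy and lesioned/rebound network models are run with paired seeds;
    seed-averaged PLV matrices (optionally with additive truncated-Gaussian
    observation noise of std ``obs_noise``) give the FC-change matrices on
    an analysis subset of ``n_subset`` regions that excludes the stroke
    node and its strongest neighbors (the peri-infarct core). The rehab
    condition defaults to partial recovery: less damage
    (``s_rehab = min(1, s_true + 0.4)``) and slightly reduced rebound.
    """
    if not 0 <= s_true <= 1 or not 0 <= r_true <= 5:
        raise ValueError("need s_true in [0,1] and r_true in [0,5]")
    if n_regions < n_subset + 2:
        raise ValueError(
            f"n_regions={n_regions} too small for a {n_subset}-region analysis subset"
        )
    kp = kp or KuramotoParams()
    if isinstance(seeds, (int, np.integer)):
        seeds = list(range(int(seeds)))
    conn = generate_synthetic_connectome(n_regions, density=density, seed=conn_seed)
    stroke = conn.stroke_region
    # peri-infarct core: the stroke node plus its strongest neighbors
    strength = conn.weights[stroke, :] + conn.weights[:, stroke]
    strength[stroke] = np.inf
    n_excluded = n_regions - n_subset
    core = np.argsort(-strength, kind="stable")[:n_excluded]
    subset_idx = np.setdiff1d(np.arange(n_regions), core)
    subset = [conn.labels[i] for i in subset_idx]

    rng = np.random.default_rng(noise_seed)
    plv_h = simulate_phase_locking(conn, kp, seeds, acc_every=acc_every).mean(axis=0)
    plv_h_obs = _observe_plv(plv_h, obs_noise, rng)

    def condition_change(s: float, r: float) -> FCChange:
        spec = LesionSpec(stroke_region=stroke, retain_fraction=s, rebound=r)
        lesioned = apply_rebound(conn, spec)
        plv_c = simulate_phase_locking(lesioned, kp, seeds, acc_every=acc_every).mean(axis=0)
        plv_c = _observe_plv(plv_c, obs_noise, rng)
        delta = (plv_c - plv_h_obs)[np.ix_(subset_idx, subset_idx)]
        np.fill_diagonal(delta, 0.0)
        return FCChange(delta=delta, labels=subset, mode="difference")

    change_stroke = condition_change(s_true, r_true)
    if s_rehab is None:
        s_rehab = min(1.0, s_true + 0.4)
    if r_rehab is None:
        r_rehab = max(0.0, r_true - 0.5)
    change_rehab = condition_change(s_rehab, r_rehab)

    manifest = {
        "n_regions": n_regions, "s_true": s_true, "r_true": r_true,
        "s_rehab": s_rehab, "r_rehab": r_rehab,
        "kp": asdict(kp), "seeds": list(map(int, seeds)),
        "obs_noise": obs_noise, "noise_seed": noise_seed,
        "conn_seed": conn_seed, "density": density, "n_subset": n_subset,
        "region_subset": subset,
    }
    return GroundTruthExperiment(
        healthy_conn=conn, s_true=s_true, r_true=r_true, kp=kp,
        seeds=list(map(int, seeds)), data_change_stroke=change_stroke,
        data_change_rehab=change_rehab, region_subset=subset, manifest=manifest,
    )


def generate_calcium_like_signals(
    conn: Connectome,
    kp: KuramotoParams | None = None,
    fs_out: float = 25.0,
    snr: float | None = None,
    confound_amplitude: float = 0.0,
    confound_freq: float = 0.2,
    seed: int = 0,
) -> SignalTimeSeries:
    """Region-wise signals emulating wide-field calcium recordings.

    The sine of simulated network phases is resampled to ``fs_out``
    (default 25 Hz, the regime of minutes-long calcium recordings with a
    12.5 Hz Nyquist frequency), white observation noise is added at the
    requested SNR (signal/noise power; None = noiseless, 0 = pure noise),
    and an optional slow (< 0.5 Hz) common confound is superposed to
    exercise the band-pass stage.
    """
    kp = kp or KuramotoParams()
    if fs_out < 2 * kp.f:
        raise ValueError(f"fs_out={fs_out} Hz cannot represent f={kp.f} Hz")
    if not 0.5 < kp.f < fs_out / 2:
        raise ValueError("kp.f must lie in (0.5, fs_out/2) Hz")
    kp_run = KuramotoParams(**{**asdict(kp), "seed": seed})
    phases = simulate_phases(conn, kp_run)
    x = np.sin(phases.phases)
    fs_in = phases.fs
    down = int(round(fs_in / fs_out))
    if abs(fs_in / fs_out - down) > 1e-9:
        raise ValueError(f"fs_out must divide the simulation rate {fs_in} Hz")
    x = spsignal.resample_poly(x, up=1, down=down, axis=1)
    rng = np.random.default_rng(seed + 1)
    sig_power = x.var(axis=1, keepdims=True).mean()
    if snr is not None:
        if snr == 0:
            x = rng.standard_normal(x.shape) * np.sqrt(sig_power)
        else:
            x = x + rng.standard_normal(x.shape) * np.sqrt(sig_power / snr)
    if confound_amplitude > 0:
        t = np.arange(x.shape[1]) / fs_out
        conf = confound_amplitude * np.sqrt(sig_power) * np.sin(
            2 * np.pi * confound_freq * t + rng.uniform(0, 2 * np.pi))
        x = x + conf[None, :]
    return SignalTimeSeries(data=x, fs=fs_out, labels=list(conn.labels))


def generate_poisson_spikes(rate: float, n_neurons: int, duration: float,
                            seed: int = 0) -> list[np.ndarray]:
    """Homogeneous Poisson spike trains (times in seconds, sorted)."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n_neurons):
        n = rng.poisson(rate * duration)
        trains.append(np.sort(rng.uniform(0.0, duration, size=n)))
    return trains
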