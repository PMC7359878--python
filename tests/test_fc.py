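import numpy as np
import pytest

from strokesim import (
    FCChange,
    FCMatrix,
    KuramotoParams,
    analytic_phase,
    bandpass_filter,
    fc_change,
    fc_from_signals,
    fit_parameter_grid,
    generate_synthetic_connectome,
    plv_matrix,
    simulate_phases,
    surrogate_significance,
)
from strokesim.containers import SignalTimeSeries
from strokesim.kuramoto import PhaseTimeSeries
from strokesim.synthetic_data import generate_ground_truth_experiment


def sine_signals(freqs, fs=25.0, duration=60.0, amps=None, noise=0.0, seed=0):
    t = np.arange(int(duration * fs)) / fs
    amps = amps or [1.0] * len(freqs)
    rng = np.random.default_rng(seed)
    data = np.stack([a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs, amps)])
    if noise:
        data = data + noise * rng.standard_normal(data.shape)
    return SignalTimeSeries(data=data, fs=fs)


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        ts = sine_signals([3.5])
        out = bandpass_filter(ts, 2.5, 5.0)
        mid = slice(200, -200)
        ratio = out.data[0, mid].std() / ts.data[0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_rejected(self):
        ts = sine_signals([0.2], duration=120.0)
        out = bandpass_filter(ts, 2.5, 5.0)
        assert np.sqrt((out.data ** 2).mean()) < 0.05 * np.sqrt((ts.data ** 2).mean())

    def test_mixture_reduces_to_passband_component(self):
        fs, duration = 25.0, 60.0
        t = np.arange(int(duration * fs)) / fs
        slow = np.sin(2 * np.pi * 0.2 * t)
        fast = np.sin(2 * np.pi * 3.5 * t)
        ts = SignalTimeSeries((slow + fast)[None, :], fs=fs)
        out = bandpass_filter(ts, 2.5, 5.0)
        mid = slice(200, -200)
        r = np.corrcoef(out.data[0, mid], fast[mid])[0, 1]
        assert r > 0.95

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(sine_signals([3.0]), 2.5, 13.0)


class TestAnalyticPhase:
    def test_sinusoid_phase_slope(self):
        ts = sine_signals([3.5])
        ph = analytic_phase(ts)
        mid = slice(200, -200)
        unwrapped = np.unwrap(ph.phases[0])
        slope = np.diff(unwrapped[mid]).mean() * ts.fs
        assert slope == pytest.approx(2 * np.pi * 3.5, rel=0.01)

    def test_quadrature_offset(self):
        fs, t = 25.0, np.arange(1500) / 25.0
        ts = SignalTimeSeries(np.stack([np.cos(2 * np.pi * 3 * t),
                                        np.sin(2 * np.pi * 3 * t)]), fs=fs)
        ph = analytic_phase(ts)
        diff = np.angle(np.exp(1j * (ph.phases[0] - ph.phases[1])))
        assert np.median(diff) == pytest.approx(np.pi / 2, abs=0.05)

    def test_amplitude_modulation_keeps_phase_slope(self):
        fs, t = 25.0, np.arange(1500) / 25.0
        am = (1 + 0.4 * np.sin(2 * np.pi * 0.1 * t)) * np.sin(2 * np.pi * 3.5 * t)
        ph = analytic_phase(SignalTimeSeries(am[None, :], fs=fs))
        mid = slice(200, -200)
        slope = np.diff(np.unwrap(ph.phases[0])[mid]).mean() * fs
        assert slope == pytest.approx(2 * np.pi * 3.5, rel=0.01)

    def test_constant_channel_rejected(self):
        ts = SignalTimeSeries(np.vstack([np.ones(200),
                                         np.sin(np.arange(200))]), fs=25.0)
        with pytest.raises(ValueError, match="constant"):
            analytic_phase(ts)


class TestPLV:
    def test_identical_phases_lock_at_one(self):
        theta = np.random.default_rng(0).uniform(-np.pi, np.pi, 500)
        ph = PhaseTimeSeries(np.stack([theta, theta]), fs=25.0)
        assert plv_matrix(ph).plv[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_locks_at_one(self):
        theta = np.random.default_rng(1).uniform(-np.pi, np.pi, 500)
        ph = PhaseTimeSeries(np.stack([theta, theta + 0.8]), fs=25.0)
        assert plv_matrix(ph).plv[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_balanced_antiphase_cancels(self):
        diff = np.tile([0.0, np.pi], 250)
        ph = PhaseTimeSeries(np.stack([diff, np.zeros(500)]), fs=25.0)
        assert plv_matrix(ph).plv[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_independent_phases_rayleigh_scale(self):
        """PLV of independent phases concentrates near sqrt(pi/4)/sqrt(M)."""
        m = 10_000
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            theta = rng.uniform(-np.pi, np.pi, (2, m))
            vals.append(plv_matrix(PhaseTimeSeries(theta, fs=1.0)).plv[0, 1])
        vals = np.array(vals)
        assert np.mean(vals < 0.03) >= 0.99
        assert vals.mean() == pytest.approx(np.sqrt(np.pi / 4) / np.sqrt(m), rel=0.1)

    @pytest.mark.parametrize("seed", range(3))
    def test_matrix_invariants_on_random_phases(self, seed):
        rng = np.random.default_rng(seed)
        ph = PhaseTimeSeries(rng.uniform(-np.pi, np.pi, (6, 300)), fs=25.0)
        mat = plv_matrix(ph)
        np.testing.assert_allclose(mat.plv, mat.plv.T)
        np.testing.assert_array_equal(np.diag(mat.plv), 1.0)
        assert mat.plv.min() >= 0 and mat.plv.max() <= 1

    def test_nan_rejected(self):
        theta = np.zeros((2, 100))
        theta[0, 3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            plv_matrix(PhaseTimeSeries(theta, fs=25.0))


class TestSurrogates:
    @staticmethod
    def _broadband_locked(m=2000, noise=0.3, seed=0, fs=25.0):
        """Two channels sharing a broadband delta-band source.

        A shared narrowband *stochastic* source (not a pure tone: the PLV
        of two pure tones of equal frequency is 1 by construction, so
        surrogates cannot bound it) plus independent noise."""
        rng = np.random.default_rng(seed)
        src = rng.standard_normal(m)
        data = np.stack([src + noise * rng.standard_normal(m),
                         src + noise * rng.standard_normal(m)])
        ts = SignalTimeSeries(data, fs=fs)
        return bandpass_filter(ts, 2.5, 5.0)

    def test_locked_channels_exceed_threshold(self):
        band = self._broadband_locked()
        thr = surrogate_significance(band, n_surrogates=25, quantile=0.95)
        obs = plv_matrix(analytic_phase(band))
        assert obs.plv[0, 1] > thr.plv[0, 1]

    def test_independent_noise_mostly_below_threshold(self):
        """At the 0.95 quantile, >= 90% of independent pairs stay below
        the surrogate threshold (expected false-positive rate 5%)."""
        below = total = 0
        iu = np.triu_indices(6, 1)
        for run in range(10):
            rng = np.random.default_rng(run)
            ts = SignalTimeSeries(rng.standard_normal((6, 1000)), fs=25.0)
            band = bandpass_filter(ts, 2.5, 5.0)
            thr = surrogate_significance(band, n_surrogates=39, quantile=0.95,
                                         seed=run)
            obs = plv_matrix(analytic_phase(band))
            below += np.sum(obs.plv[iu] < thr.plv[iu])
            total += len(iu[0])
        assert below / total >= 0.9

    def test_threshold_shrinks_with_more_samples(self):
        thrs = []
        for m in (500, 5000):
            rng = np.random.default_rng(0)
            ts = SignalTimeSeries(rng.standard_normal((2, m)), fs=25.0)
            band = bandpass_filter(ts, 2.5, 5.0)
            thr = surrogate_significance(band, n_surrogates=49, quantile=0.95)
            thrs.append(thr.plv[0, 1])
        assert thrs[1] < thrs[0]

    def test_bad_parameters_rejected(self):
        ts = sine_signals([3.0])
        with pytest.raises(ValueError):
            surrogate_significance(ts, n_surrogates=5)
        with pytest.raises(ValueError):
            surrogate_significance(ts, n_surrogates=20, quantile=1.5)


class TestFCChange:
    def test_self_change_is_zero(self):
        mat = FCMatrix(np.array([[1.0, 0.4], [0.4, 1.0]]))
        assert np.all(fc_change(mat, mat).delta == 0)

    def test_difference_mode_bounded(self):
        a = FCMatrix(np.array([[1.0, 0.9], [0.9, 1.0]]))
        b = FCMatrix(np.array([[1.0, 0.1], [0.1, 1.0]]))
        delta = fc_change(a, b).delta
        assert delta.min() >= -1 and delta.max() <= 1

    def test_relative_mode_arithmetic(self):
        cond = FCMatrix(np.array([[1.0, 0.6], [0.6, 1.0]]))
        ref = FCMatrix(np.array([[1.0, 0.4], [0.4, 1.0]]))
        assert fc_change(cond, ref, mode="relative").delta[0, 1] == \
            pytest.approx(0.5)

    def test_zero_reference_rejected_in_relative_mode(self):
        cond = FCMatrix(np.array([[1.0, 0.6], [0.6, 1.0]]))
        ref = FCMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
        with pytest.raises(ValueError, match="zero"):
            fc_change(cond, ref, mode="relative")

    def test_label_mismatch_rejected(self):
        a = FCMatrix(np.eye(2), labels=["x", "y"])
        b = FCMatrix(np.eye(2), labels=["x", "z"])
        with pytest.raises(ValueError, match="labels"):
            fc_change(a, b)


class TestPipelineParity:
    def test_phase_plv_matches_signal_pipeline(self, small_conn):
        """PLV from model phases vs sin(theta) -> band-pass -> Hilbert."""
        kp = KuramotoParams(f=2.0, duration=40.0, transient=5.0, seed=11)
        ph = simulate_phases(small_conn, kp, decimate=10)  # 100 Hz
        direct = plv_matrix(ph)
        sig = SignalTimeSeries(np.sin(ph.phases), fs=ph.fs, labels=ph.labels)
        filtered = fc_from_signals(sig, band=(1.0, 4.0))
        rms = np.sqrt(np.mean((direct.plv - filtered.plv) ** 2))
        assert rms < 0.05


class TestParameterGridFit:
    def test_closure_with_shared_seeds(self):
        """Data generated by the model itself is matched exactly at truth."""
        kp = KuramotoParams(duration=30.0, transient=5.0)
        seeds = list(range(4))
        exp = generate_ground_truth_experiment(
            18, s_true=0.4, r_true=1.0, kp=kp, seeds=seeds, obs_noise=0.0)
        res = fit_parameter_grid(exp.data_change_stroke, exp.healthy_conn, kp,
                                 s_grid=[0.2, 0.4, 0.6], r_grid=[0.5, 1.0, 1.5],
                                 seeds=seeds)
        assert res.best_s == 0.4 and res.best_r == 1.0
        assert res.best_value == pytest.approx(1.0, abs=1e-9)
        assert res.values.max() <= 1.0 + 1e-12

    def test_renaming_regions_leaves_fit_unchanged(self):
        kp = KuramotoParams(duration=20.0, transient=5.0)
        seeds = [0, 1]
        exp = generate_ground_truth_experiment(18, 0.5, 0.5, kp=kp, seeds=seeds)
        res1 = fit_parameter_grid(exp.data_change_stroke, exp.healthy_conn, kp,
                                  [0.3, 0.6], [0.0, 1.0], seeds=seeds)
        renamed_conn = exp.healthy_conn.copy()
        renamed_conn.labels = [f"area-{l}" for l in renamed_conn.labels]
        renamed_change = FCChange(delta=exp.data_change_stroke.delta,
                                  labels=[f"area-{l}"
                                          for l in exp.data_change_stroke.labels])
        res2 = fit_parameter_grid(renamed_change, renamed_conn, kp,
                                  [0.3, 0.6], [0.0, 1.0], seeds=seeds)
        np.testing.assert_array_equal(res1.values, res2.values)

    def test_constant_data_change_rejected(self, small_conn):
        change = FCChange(delta=np.zeros((12, 12)),
                          labels=small_conn.labels[6:])
        with pytest.raises(ValueError, match="zero variance"):
            fit_parameter_grid(change, small_conn, KuramotoParams(),
                               [0.5], [0.0], seeds=[0])

    def test_too_small_subset_rejected(self, small_conn):
        change = FCChange(delta=np.array([[0.0, 0.1], [0.1, 0.0]]),
                          labels=small_conn.labels[1:3])
        with pytest.raises(ValueError, match="3 analysis regions"):
            fit_parameter_grid(change, small_conn, KuramotoParams(),
                               [0.5], [0.0], seeds=[0])
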