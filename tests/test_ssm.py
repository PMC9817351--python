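import numpy as np
import pytest

import paindecode as pdz
from paindecode.ssm import DetectionConfig, ZScoreSeries

from .conftest import random_stable_params
from .oracles import dense_gaussian_moments


class TestKalmanFilter:
    def test_zero_modulation_zero_gain(self):
        """With c = 0 the observations carry no information about the state."""
        p = pdz.SSMParams(a=0.6, c=[0, 0, 0], d=[1, 1, 1], sigma2=1.0, Sigma=np.eye(3))
        rng = np.random.default_rng(0)
        est = pdz.kalman_filter(p, rng.normal(size=(20, 3)), z0=0.0)
        np.testing.assert_array_equal(est.gain, 0.0)
        np.testing.assert_array_equal(est.filt_mean, 0.0)

    def test_hand_computed_scalar_update(self):
        """One memoryless step, worked through the six filter equations."""
        p = pdz.SSMParams(a=0.0, c=[1, 0, 0], d=[0, 0, 0], sigma2=1.0, Sigma=np.eye(3))
        est = pdz.kalman_filter(p, np.array([[2.0, 0.0, 0.0]]), z0=0.0, Q0=0.0)
        assert est.filt_mean[0] == pytest.approx(1.0)
        assert est.filt_var[0] == pytest.approx(0.5)
        np.testing.assert_allclose(est.gain[0], [0.5, 0.0, 0.0])

    def test_matches_dense_conditioning_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            p = random_stable_params(rng)
            tr = pdz.simulate_ssm(p, 30, z0=0.2, seed=int(rng.integers(1 << 30)))
            est = pdz.kalman_filter(p, tr.observations, z0=0.2, Q0=0.9)
            fm, fv, _, _ = dense_gaussian_moments(p, tr.observations, 0.2, 0.9)
            np.testing.assert_allclose(est.filt_mean, fm, rtol=1e-8, atol=1e-10)
            np.testing.assert_allclose(est.filt_var, fv, rtol=1e-8, atol=1e-10)

    def test_variance_monotonicity(self):
        rng = np.random.default_rng(1)
        p = random_stable_params(rng)
        tr = pdz.simulate_ssm(p, 200, seed=5)
        est = pdz.kalman_filter(p, tr.observations)
        assert np.all(est.filt_var <= est.pred_var + 1e-12)
        assert np.all(est.filt_var >= 0) and np.all(est.pred_var >= 0)

    def test_singular_covariance_rejected(self):
        p = pdz.SSMParams(a=0.5, c=[1, 0, 0], d=[0, 0, 0], sigma2=1.0, Sigma=np.zeros((3, 3)))
        with pytest.raises(pdz.SingularCovarianceError):
            pdz.kalman_filter(p, np.ones((5, 3)))


class TestRTSSmoother:
    def test_single_bin_equals_filtered(self):
        rng = np.random.default_rng(2)
        p = random_stable_params(rng)
        est = pdz.kalman_filter(p, rng.normal(size=(1, 3)))
        sm = pdz.rts_smooth(p, est)
        assert sm.mean[0] == est.filt_mean[0]
        assert sm.var[0] == est.filt_var[0]

    def test_near_unit_root_smooths_to_constant(self):
        """As a -> 1 with vanishing state noise the smoothed trajectory is far
        flatter than the filtered one and tracks the (nearly constant) latent."""
        p = pdz.SSMParams(a=0.999, c=[1, 0.5, 0.2], d=[0, 0, 0], sigma2=1e-8, Sigma=np.eye(3))
        tr = pdz.simulate_ssm(p, 100, z0=1.0, seed=3)
        est = pdz.kalman_filter(p, tr.observations, z0=0.0, Q0=1.0)
        sm = pdz.rts_smooth(p, est)
        assert np.ptp(sm.mean) < 0.2 * np.ptp(est.filt_mean)
        assert np.ptp(sm.mean) < 0.15 * np.abs(sm.mean).mean()

    def test_matches_dense_conditioning_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            p = random_stable_params(rng)
            tr = pdz.simulate_ssm(p, 20, seed=int(rng.integers(1 << 30)))
            est = pdz.kalman_filter(p, tr.observations, z0=0.0, Q0=0.5)
            sm = pdz.rts_smooth(p, est)
            _, _, smean, svar = dense_gaussian_moments(p, tr.observations, 0.0, 0.5)
            np.testing.assert_allclose(sm.mean, smean, rtol=1e-8, atol=1e-10)
            np.testing.assert_allclose(sm.var, svar, rtol=1e-8, atol=1e-10)

    def test_smoothed_variance_not_larger_than_filtered(self):
        rng = np.random.default_rng(4)
        p = random_stable_params(rng)
        tr = pdz.simulate_ssm(p, 100, seed=9)
        est = pdz.kalman_filter(p, tr.observations)
        sm = pdz.rts_smooth(p, est)
        assert np.all(sm.var <= est.filt_var + 1e-12)

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        p = random_stable_params(rng)
        est = pdz.kalman_filter(p, rng.normal(size=(10, 3)))
        est.pred_var = est.pred_var[:5]
        with pytest.raises(pdz.InconsistentInputError):
            pdz.rts_smooth(p, est)


class TestEMFit:
    def test_ascent_from_truth(self):
        truth = pdz.SSMParams(
            a=0.8, c=[1.0, 0.5, 0.2], d=[3.0, 2.0, 1.0], sigma2=1.0, Sigma=0.5 * np.eye(3)
        )
        tr = pdz.simulate_ssm(truth, 500, seed=21)
        _, ll = pdz.em_fit(tr.observations, init=truth, max_iter=5)
        assert np.all(np.diff(ll) >= -1e-9)

    def test_parameter_recovery(self):
        truth = pdz.SSMParams(
            a=0.85, c=[1.2, 0.7, 0.3], d=[5.0, 4.0, 2.0], sigma2=0.8,
            Sigma=np.diag([1.0, 0.6, 0.4]),
        )
        tr = pdz.simulate_ssm(truth, 5000, seed=22)
        fit, ll = pdz.em_fit(tr.observations)
        assert np.all(np.diff(ll) >= -1e-9)
        assert abs(fit.a - truth.a) <= 0.05
        target = np.outer(truth.c, truth.c) * truth.stationary_var + truth.Sigma
        got = np.outer(fit.c, fit.c) * fit.stationary_var + fit.Sigma
        rel = np.linalg.norm(got - target) / np.linalg.norm(target)
        assert rel <= 0.10

    def test_degenerate_features_rejected(self):
        with pytest.raises(pdz.DegenerateInputError):
            pdz.em_fit(np.ones((50, 3)) * 2.0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(pdz.InsufficientDataError):
            pdz.em_fit(np.random.default_rng(0).normal(size=(5, 3)))


class TestZScore:
    def _series(self, filt_mean, filt_var=None, bin_size=0.1):
        K = len(filt_mean)
        p = pdz.SSMParams(a=0.5, c=[1, 0, 0], d=[0, 0, 0], sigma2=1.0, Sigma=np.eye(3))
        est = pdz.kalman_filter(p, np.zeros((K, 3)))
        est.filt_mean = np.asarray(filt_mean, dtype=float)
        if filt_var is not None:
            est.filt_var = np.asarray(filt_var, dtype=float)
        return p, est

    def test_constant_baseline_rejected(self):
        p, est = self._series(np.concatenate([np.ones(5), np.arange(5.0)]))
        with pytest.raises(pdz.DegenerateBaselineError):
            pdz.zscore_trajectory(p, est, baseline_window=(0.0, 0.5))

    def test_baseline_mean_maps_to_zero(self):
        vals = np.array([1.0, 2.0, 3.0, 2.0, 2.0, 5.0])
        p, est = self._series(vals)
        zs = pdz.zscore_trajectory(p, est, baseline_window=(0.0, 0.4))
        base_mean = vals[:4].mean()
        k = np.where(vals == base_mean)[0][0]
        assert zs.z_value[k] == pytest.approx(0.0, abs=1e-12)

    def test_invariance_under_latent_rescaling(self):
        """z -> alpha z with c -> c/alpha leaves the Z trajectory unchanged."""
        alpha = 3.7
        base = pdz.SSMParams(
            a=0.8, c=[1.0, 0.5, 0.2], d=[1.0, 1.0, 1.0], sigma2=1.0, Sigma=0.3 * np.eye(3)
        )
        scaled = pdz.SSMParams(
            a=0.8, c=np.array(base.c) / alpha, d=base.d, sigma2=alpha**2, Sigma=base.Sigma
        )
        tr = pdz.simulate_ssm(base, 60, seed=33)
        e1 = pdz.kalman_filter(base, tr.observations)
        e2 = pdz.kalman_filter(scaled, tr.observations)
        z1 = pdz.zscore_trajectory(base, e1, baseline_window=(0.0, 2.0))
        z2 = pdz.zscore_trajectory(scaled, e2, baseline_window=(0.0, 2.0))
        np.testing.assert_allclose(z1.z_value, z2.z_value, rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(z1.ci_half_width, z2.ci_half_width, rtol=1e-6, atol=1e-9)


class TestDetectOnset:
    def _zs(self, z, ci):
        z = np.asarray(z, dtype=float)
        return ZScoreSeries(
            z_value=z,
            ci_half_width=np.full(z.size, float(ci)),
            baseline_mean=0.0,
            baseline_sd=1.0,
            baseline_window=(0.0, 0.5),
            bin_size=0.1,
            t0=0.0,
        )

    def test_null_series_not_detected(self):
        res = pdz.detect_onset(self._zs(np.zeros(10), 0.5), 0.5, response_window=(0.5, 1.0))
        assert not res.detected and res.onset_time is None

    def test_lower_bound_above_threshold_detected(self):
        z = np.zeros(10); z[6] = 5.0
        res = pdz.detect_onset(self._zs(z, 1.0), 0.5, response_window=(0.5, 1.0))
        assert res.detected  # 5.0 - 1.0 = 4.0 > 3.38
        assert res.onset_time == pytest.approx(0.6)
        assert res.direction == "positive"

    def test_subthreshold_and_negative_cases(self):
        z = np.zeros(10); z[6] = 3.5
        res = pdz.detect_onset(self._zs(z, 0.5), 0.5, response_window=(0.5, 1.0))
        assert not res.detected  # 3.0 <= 3.38
        z2 = np.zeros(10); z2[7] = -5.0
        res2 = pdz.detect_onset(self._zs(z2, 1.0), 0.5, response_window=(0.5, 1.0))
        assert res2.detected and res2.direction == "negative"
        assert res2.peak_latency == pytest.approx(0.2)

    def test_empty_response_window_rejected(self):
        with pytest.raises(pdz.InvalidWindowError):
            pdz.detect_onset(self._zs(np.zeros(10), 0.5), 0.5, response_window=(2.0, 2.05))

    def test_onset_not_after_peak_in_typical_case(self):
        z = np.zeros(12); z[5:9] = [4.0, 6.0, 8.0, 5.0]
        res = pdz.detect_onset(self._zs(z, 0.5), 0.0, response_window=(0.0, 1.2))
        assert res.detected and res.onset_time <= res.peak_latency
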