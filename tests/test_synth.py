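import numpy as np
import pytest

import paindecode as pdz
from paindecode.synth import erp_waveform


class TestBaselineLFP:
    def test_length_and_rms(self):
        rec = pdz.generate_baseline_lfp(1, 10.0, 2000.0, 50.0, seed=7)
        assert rec.n_samples == 20_000
        rms = np.sqrt(np.mean(rec.data**2))
        assert 45.0 <= rms <= 55.0

    def test_determinism(self):
        a = pdz.generate_baseline_lfp(2, 5.0, 2000.0, 50.0, seed=7)
        b = pdz.generate_baseline_lfp(2, 5.0, 2000.0, 50.0, seed=7)
        np.testing.assert_array_equal(a.data, b.data)
        c = pdz.generate_baseline_lfp(2, 5.0, 2000.0, 50.0, seed=8)
        assert not np.array_equal(a.data, c.data)

    def test_one_over_f_spectrum(self):
        from scipy import signal

        rec = pdz.generate_baseline_lfp(2, 10.0, 2000.0, 50.0, seed=7)
        for ch in rec.data:
            f, pxx = signal.welch(ch, fs=rec.fs, nperseg=4096)
            p10 = pxx[np.argmin(np.abs(f - 10.0))]
            p100 = pxx[np.argmin(np.abs(f - 100.0))]
            assert p10 > p100

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(pdz.InvalidSamplingRateError):
            pdz.generate_baseline_lfp(1, 1.0, 500.0, 50.0, seed=0)


class TestInjectERP:
    def test_zero_amplitude_is_identity(self, quiet_recording):
        out = pdz.inject_erp(quiet_recording, 1.0, 0.12, 0.0, 0.05)
        np.testing.assert_array_equal(out.data, quiet_recording.data)

    def test_peak_placement(self, quiet_recording):
        out = pdz.inject_erp(quiet_recording, 1.0, 0.12, 200.0, 0.05)
        i = np.argmax(np.abs(out.data[0]))
        assert abs(i / out.fs - 1.12) <= 1.0 / out.fs

    def test_outside_window_untouched(self, quiet_recording):
        out = pdz.inject_erp(quiet_recording, 1.0, 0.12, 200.0, 0.01)
        w, half = erp_waveform(out.fs, 200.0, 0.01)
        peak = out.sample_index(1.12)
        mask = np.ones(out.n_samples, dtype=bool)
        mask[peak - half : peak + half + 1] = False
        np.testing.assert_array_equal(out.data[:, mask], quiet_recording.data[:, mask])

    def test_window_beyond_trace_raises(self, quiet_recording):
        with pytest.raises(pdz.OutOfRangeError):
            pdz.inject_erp(quiet_recording, quiet_recording.duration - 0.01, 0.1, 50.0, 0.05)

    def test_round_trip_through_erp_module(self):
        """Planted latency is recovered within 10 ms at high SNR."""
        rec = pdz.generate_baseline_lfp(1, 8.0, 2000.0, 50.0, seed=3, rhythm_amplitude=150.0)
        rec = pdz.inject_erp(rec, 3.0, 0.13, 700.0, 0.006)
        tw = pdz.extract_trial(rec, {"stimulus_onset_s": 3.0}, ["ch00"], "mechanical")
        res = pdz.erp_peak_latency(tw)
        assert res.latency is not None
        assert abs(res.latency - 0.13) <= 0.010


class TestInjectBandPowerTransient:
    def test_identity_gain(self):
        rec = pdz.generate_baseline_lfp(1, 6.0, 2000.0, 50.0, seed=5)
        out = pdz.inject_band_power_transient(
            rec, 2.0, 0.1, "step_decay", {"30-50": 1.0, "50-100": 1.0}, 0.5
        )
        np.testing.assert_array_equal(out.data, rec.data)

    def test_unknown_band_rejected(self):
        rec = pdz.generate_baseline_lfp(1, 4.0, 2000.0, 50.0, seed=5)
        with pytest.raises(pdz.InvalidBandError):
            pdz.inject_band_power_transient(rec, 1.0, 0.1, "step_decay", {"10-20": 2.0}, 0.5)

    def test_step_decay_raises_envelope(self):
        rec = pdz.generate_baseline_lfp(1, 10.0, 2000.0, 50.0, seed=6)
        out = pdz.inject_band_power_transient(rec, 4.0, 0.1, "step_decay", {"30-50": 3.0}, 0.5)
        env = pdz.band_envelope(out.data[0], out.fs, pdz.band_by_name("30-50"))
        on = out.sample_index(4.1)
        resp = env[on : out.sample_index(4.6)].mean()
        base = env[out.sample_index(2.0) : out.sample_index(4.0)].mean()
        assert resp >= 2.0 * base

    def test_ramp_is_monotone(self):
        rec = pdz.generate_baseline_lfp(1, 12.0, 2000.0, 50.0, seed=6)
        out = pdz.inject_band_power_transient(rec, 4.0, 0.0, "ramp", {"30-50": 4.0}, 4.0)
        env = pdz.band_envelope(out.data[0], out.fs, pdz.band_by_name("30-50"))
        early = env[out.sample_index(4.8) : out.sample_index(5.2)].mean()
        late = env[out.sample_index(7.3) : out.sample_index(7.7)].mean()
        assert early < late

    def test_outside_window_bit_identical(self):
        rec = pdz.generate_baseline_lfp(1, 8.0, 2000.0, 50.0, seed=9)
        out = pdz.inject_band_power_transient(rec, 3.0, 0.1, "step_decay", {"50-100": 2.5}, 0.5)
        i0, i1 = out.sample_index(3.1), out.sample_index(3.6)
        np.testing.assert_array_equal(out.data[:, :i0], rec.data[:, :i0])
        np.testing.assert_array_equal(out.data[:, i1:], rec.data[:, i1:])


class TestGenerateSession:
    def test_mechanical_ground_truth_structure(self):
        proto = pdz.mechanical_protocol(n_trials=8, seed=1, jitter_sd=0.0)
        _, events, gt = pdz.generate_session(proto)
        assert len(gt) == 16
        assert len(events) == 8
        wide = gt.pivot(index="trial_id", columns="region", values="planted_latency_s")
        np.testing.assert_allclose(wide["ACC"] - wide["S1"], 0.10)

    def test_thermal_equal_latencies(self):
        proto = pdz.thermal_protocol(n_trials=4, seed=1, jitter_sd=0.0)
        _, events, gt = pdz.generate_session(proto)
        wide = gt.pivot(index="trial_id", columns="region", values="planted_latency_s")
        np.testing.assert_allclose(wide["ACC"] - wide["S1"], 0.0)
        assert np.all(events["withdrawal_s"] > events["stimulus_onset_s"] + 3.0)

    def test_infeasible_iti_rejected(self):
        with pytest.raises(pdz.ProtocolInfeasibleError):
            proto = pdz.mechanical_protocol(n_trials=4, inter_trial_interval=0.8, seed=0)
            pdz.generate_session(proto)

    def test_session_determinism(self):
        proto = pdz.mechanical_protocol(n_trials=3, seed=17)
        r1, e1, g1 = pdz.generate_session(proto)
        r2, e2, g2 = pdz.generate_session(proto)
        for name in r1:
            np.testing.assert_array_equal(r1[name].data, r2[name].data)
        assert e1.equals(e2) and g1.equals(g2)

    def test_trial_substreams_stable_under_trial_count(self):
        """Adding trials does not reshuffle earlier trials' draws."""
        g_small = pdz.generate_session(pdz.thermal_protocol(n_trials=3, seed=4))[2]
        g_big = pdz.generate_session(pdz.thermal_protocol(n_trials=6, seed=4))[2]
        small = g_small.set_index(["trial_id", "region"]).planted_latency_s
        big = g_big.set_index(["trial_id", "region"]).planted_latency_s
        np.testing.assert_allclose(small, big.loc[small.index])


class TestSimulateSSM:
    def test_noise_free_degenerate_case(self):
        p = pdz.SSMParams(a=0.5, c=[1, 1, 1], d=[2, 3, 4], sigma2=0.0, Sigma=np.zeros((3, 3)))
        tr = pdz.simulate_ssm(p, 20, z0=0.0, seed=0)
        np.testing.assert_array_equal(tr.latent, 0.0)
        np.testing.assert_array_equal(tr.observations, np.tile([2.0, 3.0, 4.0], (20, 1)))

    def test_stationary_variance(self):
        p = pdz.SSMParams(a=0.9, c=[1, 0, 0], d=[0, 0, 0], sigma2=1.0, Sigma=np.eye(3))
        tr = pdz.simulate_ssm(p, 50_000, seed=2)
        target = 1.0 / (1.0 - 0.81)
        assert abs(tr.latent.var() - target) / target < 0.05

    def test_determinism_and_exact_model_identities(self):
        p = pdz.SSMParams(a=0.7, c=[1, 0.5, 0.2], d=[1, 2, 3], sigma2=0.5, Sigma=0.2 * np.eye(3))
        t1 = pdz.simulate_ssm(p, 100, z0=0.3, seed=11)
        t2 = pdz.simulate_ssm(p, 100, z0=0.3, seed=11)
        np.testing.assert_array_equal(t1.latent, t2.latent)
        np.testing.assert_array_equal(t1.observations, t2.observations)
        # exact reconstruction from the stored noise
        z_prev = np.concatenate(([0.3], t1.latent[:-1]))
        np.testing.assert_array_equal(t1.latent, p.a * z_prev + t1.state_noise)
        np.testing.assert_array_equal(
            t1.observations, t1.latent[:, None] * p.c + p.d + t1.obs_noise
        )

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(pdz.InvalidCovarianceError):
            pdz.SSMParams(a=0.5, c=[1, 0, 0], d=[0, 0, 0], sigma2=1.0, Sigma=-np.eye(3))
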