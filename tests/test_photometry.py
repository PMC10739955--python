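"""Photometry preprocessing: op-level oracles and chain-level recovery."""

import numpy as np
import pytest

from crhmem import photometry as ph
from crhmem import synthetic as sy
from conftest import make_photometry_spec


def _session(n=1000, rate=100.0, **kw):
    rng = np.random.default_rng(0)
    sig = kw.pop("signal", rng.normal(1, 0.01, n))
    ref = kw.pop("reference", rng.normal(1, 0.01, n))
    return ph.PhotometrySession(sig, ref, rate, kw.pop("ann", {}))


class TestTrim:
    def test_900s_session_keeps_300s(self):
        s = _session(n=90000)
        out = ph.trim_session(s)
        assert out.duration_s == pytest.approx(300.0)

    def test_600s_session_rejected(self):
        with pytest.raises(ValueError):
            ph.trim_session(_session(n=60000))

    def test_annotations_reindexed(self):
        s = _session(n=90000, ann={"ctx": (400.0, 520.0)})
        out = ph.trim_session(s)
        assert out.epoch_annotations["ctx"] == pytest.approx((100.0, 220.0))


class TestDetrend:
    def test_quadratic_removed_to_machine_precision(self):
        t = np.arange(60000) / 100.0
        chan = 2e-7 * t ** 2 - 3e-4 * t + 1.2
        out, coef = ph.detrend_polynomial(chan, 100.0, fit_windows=[(0, 600)])
        assert np.abs(out).max() < 1e-9
        assert coef == pytest.approx([2e-7, -3e-4, 1.2], rel=1e-6)

    def test_constant_input_gives_zero_and_constant_coeff(self):
        out, coef = ph.detrend_polynomial(np.full(5000, 3.0), 100.0,
                                          fit_windows=[(0, 50)])
        assert np.abs(out).max() < 1e-9
        assert coef[2] == pytest.approx(3.0)
        assert abs(coef[0]) < 1e-12 and abs(coef[1]) < 1e-10

    def test_coefficients_recovered_despite_mid_session_transient(self):
        spec = make_photometry_spec(7)
        sess, truth = sy.generate_photometry_session(spec)
        _, coef = ph.detrend_polynomial(sess.signal, sess.rate_hz)
        true = np.asarray(truth.bleach_coeffs_sig) * truth.baseline_level
        assert np.all(np.abs(coef - true) / np.abs(true) < 0.01)

    def test_underdetermined_fit_rejected(self):
        with pytest.raises(ph.UnderdeterminedFitError):
            ph.detrend_polynomial(np.ones(100), 100.0, fit_windows=[(0, 0.02)])


class TestReferenceFit:
    def test_identity(self):
        x = np.random.default_rng(1).normal(0, 1, 500)
        fitted, a, b = ph.fit_reference(x, x)
        assert a == pytest.approx(1.0) and b == pytest.approx(0.0, abs=1e-12)

    def test_affine_inversion(self):
        sig = np.random.default_rng(2).normal(0, 1, 500)
        ref = 2 * sig - 3
        fitted, a, b = ph.fit_reference(ref, sig)
        assert a == pytest.approx(0.5) and b == pytest.approx(1.5)
        assert np.allclose(fitted, sig)

    def test_uncorrelated_reference_shrinks_to_mean(self):
        rng = np.random.default_rng(3)
        sig, ref = rng.normal(5, 1, 20000), rng.normal(0, 1, 20000)
        fitted, a, _ = ph.fit_reference(ref, sig)
        assert abs(a) < 0.05
        assert np.abs(fitted - sig.mean()).max() < 0.3

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError):
            ph.fit_reference(np.ones(100), np.arange(100.0))


class TestDeltaFAndDff:
    def test_identical_channels_zero(self):
        x = np.random.default_rng(0).normal(1, 0.1, 100)
        assert np.allclose(ph.delta_f(x, x), 0)

    def test_common_mode_artifact_cancels(self):
        t = np.arange(2000) / 100.0
        motion = 0.5 * np.exp(-0.5 * ((t - 10) / 0.2) ** 2)
        base_s, base_r = np.full_like(t, 1.0), np.full_like(t, 0.8)
        sig_d, _ = ph.detrend_polynomial(base_s + motion, 100.0, fit_windows=[(0, 20)])
        ref_d, _ = ph.detrend_polynomial(base_r + motion, 100.0, fit_windows=[(0, 20)])
        fitted, a, _ = ph.fit_reference(ref_d, sig_d)
        assert a == pytest.approx(1.0, abs=1e-6)
        assert np.abs(ph.delta_f(sig_d, fitted)).max() < 1e-6

    def test_dff_exact_ratios(self):
        ref = np.linspace(1.0, 0.8, 1000)
        assert np.allclose(ph.dff(ref.copy(), ref), 0)
        # with an already-fitted reference the ratio is exact ...
        assert np.allclose(ph.dff(1.1 * ref, ref, fit=False), 0.1)
        # ... and refitting absorbs a pure gain mismatch entirely
        assert np.allclose(ph.dff(1.1 * ref, ref), 0.0, atol=1e-12)

    def test_dff_recovers_small_transient_on_matched_bleach(self):
        t = np.arange(90000) / 100.0
        bleach = np.polyval((5e-8, -3e-4, 1.0), t)
        transient = 0.05 * np.exp(-np.maximum(t - 400, 0) / 2.0) * (t >= 400)
        sig = bleach * (1.0 + transient)
        ref = np.polyval((4e-8, -2.5e-4, 0.9), t)
        out = ph.dff(sig, ref)
        base = np.median(out[(t > 390) & (t < 399)])
        assert out.max() - base == pytest.approx(0.05, abs=0.005)

    def test_dff_guards_nonpositive_fit(self):
        ref = np.linspace(1, -0.5, 100)
        with pytest.raises(ValueError, match="sample"):
            ph.dff(ref.copy(), ref)


class TestZscore:
    def test_baseline_mean_zero_sd_one_same_day(self):
        rng = np.random.default_rng(4)
        trace = rng.normal(2, 0.5, 3000)
        z = ph.zscore(trace, 100.0, (0.0, 30.0))
        assert z.values.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.values.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_value(self):
        trace = np.array([0.0, 0.0, 1.0, 1.0, 1.0774])
        z = ph.zscore(trace, 1.0, (0.0, 4.0))
        # baseline {0,0,1,1}: mean 0.5, sd (n-1) = 0.57735 -> z(1.0774) = 1.0
        assert z.values[-1] == pytest.approx(1.0, abs=1e-3)
        assert z.method == "zscore"

    def test_day1_sigma_scales_amplitudes(self):
        rng = np.random.default_rng(5)
        trace = rng.normal(0, 1, 2000)
        same = ph.zscore(trace, 100.0, (0.0, 10.0))
        sigma1 = 2 * same.baseline_stats["sigma_F"]
        cross = ph.zscore(trace, 100.0, (0.0, 10.0), sd_source="day-1",
                          day1_sigma=sigma1)
        assert np.allclose(cross.values, same.values / 2)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            ph.zscore(np.ones(100), 100.0, (0.0, 0.5))


class TestEpochMean:
    def test_constant_and_single_sample_and_ramp(self):
        assert ph.epoch_mean(np.full(100, 3.3), 10.0, (0, 10)) == pytest.approx(3.3)
        assert ph.epoch_mean(np.arange(10.0), 10.0, (0.5, 0.6)) == pytest.approx(5.0)
        ramp = np.linspace(0, 1, 1001)
        assert ph.epoch_mean(ramp, 100.0, (0, 10.01)) == pytest.approx(0.5, abs=1e-3)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            ph.epoch_mean(np.arange(10.0), 10.0, (5.0, 5.0))


class TestChainRecovery:
    """detrend -> fit -> dF recovers generator ground truth."""

    @pytest.mark.parametrize("seed", range(8))
    def test_event_amplitude_within_five_percent(self, seed):
        sess, truth = sy.generate_photometry_session(make_photometry_spec(seed))
        sig_d, _ = ph.detrend_polynomial(sess.signal, sess.rate_hz)
        ref_d, _ = ph.detrend_polynomial(sess.reference, sess.rate_hz)
        fitted, _, _ = ph.fit_reference(ref_d, sig_d)
        df = ph.delta_f(sig_d, fitted)
        t = sess.time_s
        for tt in truth.event_times_s:
            w = (t >= tt) & (t < tt + 0.5)
            pre = (t >= tt - 5) & (t < tt - 0.1)
            measured = df[w].mean() - np.median(df[pre])
            expected = truth.event_component[w].mean() - truth.event_component[pre].mean()
            assert measured == pytest.approx(expected, rel=0.05)

    def test_process_session_full_chain(self):
        spec = make_photometry_spec(11)
        sess, _ = sy.generate_photometry_session(spec)
        sess.epoch_annotations["home_cage"] = (0.0, 180.0)
        z = ph.process_session(sess, method="zscore", baseline="home_cage")
        assert z.method == "zscore" and len(z.values) == sess.n_samples
        d = ph.process_session(sess, method="deltaF")
        assert d.method == "deltaF"


class TestSessionIO:
    def test_h5_and_csv_roundtrip(self, tmp_path):
        sess, _ = sy.generate_photometry_session(
            sy.SyntheticPhotometrySpec(duration_s=5, noise_sd=0.01, seed=0))
        sess.epoch_annotations["home_cage"] = (0.0, 2.0)
        p = tmp_path / "s.h5"
        ph.write_session_h5(sess, p)
        back = ph.read_session_h5(p)
        assert np.allclose(back.signal, sess.signal)
        assert back.epoch_annotations["home_cage"] == (0.0, 2.0)
        c = tmp_path / "s.csv"
        ph.write_session_csv(sess, c)
        back2 = ph.read_session_csv(c)
        assert np.allclose(back2.reference, sess.reference)
        assert back2.rate_hz == pytest.approx(sess.rate_hz)
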