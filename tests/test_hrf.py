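"""Transfer-function prediction, goodness of fit, and parameter recovery."""

import numpy as np
import pytest

from obnvc.core import GammaHRF, HRF_INIT, gamma_variate
from obnvc.hrf import fit_transfer_function, goodness_of_fit, predict_bv
from obnvc.neural import FiringRateEstimate
from obnvc.synth import make_firing_rate

RATE_HZ = 25.0


def _aligned_rate(conc=3.0, gain=1.0):
    """Odor-evoked rate on the standard 575-sample aligned grid."""
    r = make_firing_rate(4.0, 4.0, conc, gain, rate_hz=RATE_HZ, total_s=19.0)
    r = np.concatenate([r, np.zeros(100)])
    return FiringRateEstimate(r, RATE_HZ, clip_applied=False)


class TestPredictBv:
    def test_unit_area_impulse_reproduces_kernel(self):
        n = 575
        dt = 1.0 / RATE_HZ
        rate = np.zeros(n)
        rate[100] = 1.0 / dt
        hrf = GammaHRF(0.8, 4.0, 3.0, 0.2)
        pred = predict_bv(rate, hrf, frame_rate_hz=RATE_HZ)
        t = np.arange(n - 100) / RATE_HZ
        np.testing.assert_allclose(pred[100:], gamma_variate(t, hrf), atol=1e-12)
        assert np.all(pred[:100] == 0)

    def test_zero_amplitude_zero_prediction(self):
        rate = _aligned_rate()
        pred = predict_bv(rate, GammaHRF(1e-30, 4.0, 3.0, 0.2))
        np.testing.assert_allclose(pred, 0.0, atol=1e-25)

    def test_boxcar_peak_later_than_impulse_peak(self):
        """Convolving with a sustained drive delays the response peak
        relative to the impulse response (brute-force convolution oracle)."""
        hrf = GammaHRF(*HRF_INIT)
        dt = 1.0 / RATE_HZ
        n = 575
        t = np.arange(n) / RATE_HZ
        impulse = np.zeros(n)
        impulse[100] = 1.0
        box = ((t >= 4.0) & (t < 8.0)).astype(float)
        brute = np.array([np.sum(box[: i + 1] * gamma_variate(
            (i - np.arange(i + 1)) * dt, hrf)) * dt for i in range(n)])
        pred_box = predict_bv(box, hrf, frame_rate_hz=RATE_HZ)
        np.testing.assert_allclose(pred_box, brute, atol=1e-10)
        assert np.argmax(pred_box) > np.argmax(
            predict_bv(impulse, hrf, frame_rate_hz=RATE_HZ))


class TestGoodnessOfFit:
    def test_identical_traces(self):
        y = np.sin(np.linspace(0, 6, 500))
        gof, lag, flagged = goodness_of_fit(y, y)
        assert gof == pytest.approx(1.0)
        assert lag == 0 and not flagged

    def test_one_frame_shift_detected(self):
        y = np.exp(-((np.arange(500) - 250.0) / 5) ** 2)
        shifted = np.concatenate([[0.0], y[:-1]])  # prediction delayed 1 frame
        gof, lag, _ = goodness_of_fit(y, shifted)
        assert lag == 1
        assert gof > 0.99

    def test_anticorrelated_at_zero_lag(self):
        y = np.sin(np.linspace(0, 6, 500))
        gof, lag, _ = goodness_of_fit(y, -y, max_lag_frames=0)
        assert gof == pytest.approx(-1.0)
        assert lag == 0

    def test_zero_variance_flagged(self):
        gof, lag, flagged = goodness_of_fit(np.zeros(100), np.ones(100))
        assert (gof, lag, flagged) == (0.0, 0, True)


class TestFitTransferFunction:
    def test_noiseless_recovery_from_offset_truth(self):
        """Starting from the standard initial values, a noiseless fit
        recovers a different true parameter set to 0.1%."""
        h_true = GammaHRF(1.3, 3.1, 2.4, 0.6)
        rate = _aligned_rate()
        bv_oriented = predict_bv(rate, h_true)
        res = fit_transfer_function(rate, -bv_oriented)
        assert res.converged
        for got, want in zip(res.hrf.as_tuple(), h_true.as_tuple()):
            assert got == pytest.approx(want, rel=1e-3)
        assert res.gof_max_xcorr > 1 - 1e-8
        assert res.n_iterations <= 700

    def test_rate_scaling_inverts_amplitude_only(self):
        h_true = GammaHRF(*HRF_INIT)
        rate1 = _aligned_rate(gain=1.0)
        bv = predict_bv(rate1, h_true)
        rate3 = _aligned_rate(gain=3.0)
        res = fit_transfer_function(rate3, -bv)
        assert res.hrf.y_m == pytest.approx(h_true.y_m / 3.0, rel=1e-3)
        assert res.hrf.t_m == pytest.approx(h_true.t_m, rel=1e-3)
        assert res.hrf.alpha == pytest.approx(h_true.alpha, rel=1e-2)
        assert res.hrf.y_0 == pytest.approx(h_true.y_0, abs=1e-3)

    def test_noisy_recovery_reasonable(self):
        h_true = GammaHRF(*HRF_INIT)
        rate = _aligned_rate()
        clean = predict_bv(rate, h_true)
        rng = np.random.default_rng(9)
        errs = []
        for _ in range(10):
            noisy = clean + rng.normal(0, clean.max() / 20, clean.size)
            res = fit_transfer_function(rate, -noisy)
            errs.append(abs(res.hrf.t_m - h_true.t_m) / h_true.t_m)
        assert np.median(errs) < 0.10

    def test_degenerate_inputs_rejected(self):
        rate = _aligned_rate()
        zero_rate = FiringRateEstimate(np.zeros(575), RATE_HZ)
        with pytest.raises(ValueError, match="no neural drive"):
            fit_transfer_function(zero_rate, np.zeros(575))
        bad = predict_bv(rate, GammaHRF(*HRF_INIT))
        bad[10] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            fit_transfer_function(rate, bad)

    def test_recovery_from_jittered_initializations(self):
        """Initial guesses within +-50% of truth converge to the optimum."""
        h_true = GammaHRF(0.8, 4.0, 3.0, 0.2)
        rate = _aligned_rate()
        bv = predict_bv(rate, h_true)
        rng = np.random.default_rng(10)
        for _ in range(5):
            init = np.array(h_true.as_tuple()) * rng.uniform(0.5, 1.5, 4)
            res = fit_transfer_function(rate, -bv, init=tuple(init),
                                        multistart=False)
            assert res.hrf.t_m == pytest.approx(4.0, rel=1e-3)
            assert res.hrf.y_m == pytest.approx(0.8, rel=1e-3)
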