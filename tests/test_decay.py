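import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iondiff import (DiffusionDecayFit, GradientDecaySeries, PulseParams,
                     attenuation, b_factor, calibrate_gradient, fit_diffusion,
                     fit_storage_decay)
from iondiff.simulate import DEFAULT_GRADIENTS

from conftest import D_F


class TestBFactor:
    def test_zero_gradient(self, pulse_params):
        assert b_factor(pulse_params, 0.0) == 0.0

    def test_hand_evaluated_value(self, pulse_params):
        # (gamma g delta)^2 (Delta - delta/3 - tau/2) at g = 2.65 T/m
        assert b_factor(pulse_params, 2.65) == pytest.approx(2.70e9, rel=5e-3)

    def test_quadratic_in_g(self, pulse_params):
        assert b_factor(pulse_params, 2.0) == pytest.approx(
            4.0 * b_factor(pulse_params, 1.0), rel=1e-12)

    def test_nonpositive_diffusion_time_rejected(self):
        with pytest.raises(ValueError, match="effective diffusion time"):
            PulseParams(delta=60e-3, Delta=20e-3, tau=0.0)


class TestAttenuation:
    def test_unity_at_zero_gradient(self, pulse_params):
        assert attenuation(1e-9, pulse_params, 0.0) == 1.0

    def test_strong_gradient_exceeds_85_percent(self, pulse_params):
        # DNA-solution Na+ at the 265 G/cm maximum gradient
        frac = 1.0 - attenuation(0.883e-9, pulse_params, 2.65)
        assert frac >= 0.85

    def test_conventional_gradient_below_10_percent(self, pulse_params):
        frac = 1.0 - attenuation(0.883e-9, pulse_params, 0.55)
        assert frac <= 0.10

    @given(st.floats(0.1, 3.0), st.floats(0.1, 3.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_nonincreasing_in_g(self, g1, g2):
        p = PulseParams(delta=2e-3, Delta=20e-3, tau=0.2e-3)
        lo, hi = sorted([g1, g2])
        assert attenuation(1e-9, p, hi) <= attenuation(1e-9, p, lo)

    def test_monotone_in_D_and_delta(self):
        p1 = PulseParams(delta=2e-3, Delta=20e-3)
        p2 = PulseParams(delta=4e-3, Delta=20e-3)
        assert attenuation(2e-9, p1, 1.0) < attenuation(1e-9, p1, 1.0)
        assert attenuation(1e-9, p2, 1.0) < attenuation(1e-9, p1, 1.0)


class TestFitDiffusion:
    def _series(self, D, params, g=None, I0=1.0):
        g = DEFAULT_GRADIENTS if g is None else np.asarray(g)
        return GradientDecaySeries(g, I0 * attenuation(D, params, g), params)

    def test_noiseless_recovery(self, pulse_params):
        fit = fit_diffusion(self._series(1.0e-9, pulse_params))
        assert fit.D == pytest.approx(1.0e-9, rel=1e-6)
        assert fit.converged

    def test_two_point_closed_form(self, pulse_params):
        # D = ln(I1/I2) / (b2 - b1), evaluated on an exact 3-point series
        g = np.array([0.2, 1.0, 2.0])
        series = self._series(0.9e-9, pulse_params, g=g)
        b = b_factor(pulse_params, g)
        closed = np.log(series.I[0] / series.I[2]) / (b[2] - b[0])
        fit = fit_diffusion(series)
        assert fit.D == pytest.approx(closed, rel=1e-10)

    def test_scale_invariance(self, pulse_params):
        s1 = self._series(1.251e-9, pulse_params)
        s2 = self._series(1.251e-9, pulse_params, I0=137.0)
        f1, f2 = fit_diffusion(s1), fit_diffusion(s2)
        assert f1.D == pytest.approx(f2.D, rel=1e-10)
        assert f2.I0 == pytest.approx(137.0 * f1.I0, rel=1e-8)

    def test_log_residual_slope_zero_on_noiseless(self, pulse_params):
        series = self._series(1.0e-9, pulse_params)
        fit = fit_diffusion(series)
        b = b_factor(pulse_params, series.g)
        log_resid = np.log(series.I) - (np.log(fit.I0) - fit.D * b)
        slope = np.polyfit(b, log_resid, 1)[0]
        assert abs(slope * np.max(b)) < 1e-8  # dimensionless slope

    def test_monte_carlo_recovery_1pct_noise(self, pulse_params):
        # 25 gradients 0.02-2.65 T/m, true D = 1.251e-9, 200 seeds
        rng = np.random.default_rng(42)
        clean = attenuation(D_F, pulse_params, DEFAULT_GRADIENTS)
        estimates = []
        for _ in range(200):
            I = clean * (1.0 + rng.normal(0, 0.01, clean.shape))
            s = GradientDecaySeries(DEFAULT_GRADIENTS, I, pulse_params)
            estimates.append(fit_diffusion(s).D)
        assert np.mean(estimates) == pytest.approx(D_F, rel=0.02)

    def test_too_few_gradients_rejected(self, pulse_params):
        with pytest.raises(ValueError, match="3 distinct"):
            GradientDecaySeries([0.1, 0.1, 0.2], [1.0, 1.0, 0.9], pulse_params)

    def test_estimator_sklearn_clone(self, pulse_params):
        from sklearn.base import clone
        est = DiffusionDecayFit(pulse_params, weighting="inverse-variance")
        cloned = clone(est)
        assert cloned.get_params()["weighting"] == "inverse-variance"


class TestCalibration:
    def test_identity_when_matching(self, pulse_params):
        g = DEFAULT_GRADIENTS
        series = GradientDecaySeries(g, attenuation(1.63e-9, pulse_params, g),
                                     pulse_params)
        assert calibrate_gradient(series, 1.63e-9) == pytest.approx(1.0, rel=1e-8)

    def test_overstated_gradients_give_scale(self, pulse_params):
        # data generated with true g, read in with nominal g = true/1.1:
        # the fitted D overshoots by 1.1^2 and the scale recovers 1.1
        g_true = DEFAULT_GRADIENTS
        I = attenuation(1.63e-9, pulse_params, g_true)
        series = GradientDecaySeries(g_true / 1.1, I, pulse_params)
        s = calibrate_gradient(series, 1.63e-9)
        assert s == pytest.approx(1.1, rel=1e-6)

    def test_quadratic_dependence(self, pulse_params):
        g = DEFAULT_GRADIENTS
        series = GradientDecaySeries(g, attenuation(4 * 1.63e-9, pulse_params, g),
                                     pulse_params)
        assert calibrate_gradient(series, 1.63e-9) == pytest.approx(2.0, rel=1e-6)


class TestStorageDecay:
    def test_noiseless_rate_recovery(self):
        t = np.linspace(0.0, 0.2, 8)
        fit = fit_storage_decay(t, 3.0 * np.exp(-20.0 * t))
        assert fit.estimate["rate"] == pytest.approx(20.0, rel=1e-6)

    def test_constant_intensity_gives_zero_rate(self):
        t = np.linspace(0.0, 0.2, 5)
        fit = fit_storage_decay(t, np.full(5, 2.0))
        assert fit.estimate["rate"] == pytest.approx(0.0, abs=1e-8)

    def test_two_point_closed_form_agreement(self):
        t = np.array([0.01, 0.05, 0.09])
        I = 1.7 * np.exp(-35.0 * t)
        closed = np.log(I[0] / I[2]) / (t[2] - t[0])
        fit = fit_storage_decay(t, I)
        assert fit.estimate["rate"] == pytest.approx(closed, rel=1e-10)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_storage_decay([0.0, 0.1, 0.2], [1.0, -0.1, 0.5])
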