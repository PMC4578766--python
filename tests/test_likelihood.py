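"""Gaussian and censored-observation likelihood."""

import math

import numpy as np
import pytest

from bayesgrowth.growth_model import GrowthParams
from bayesgrowth.likelihood import (
    DETECTION_THRESHOLDS,
    GrowthCurve,
    NoiseSpec,
    censored_point_loglik,
    curve_loglik,
    gaussian_loglik,
    joint_loglik,
    make_curve_loglik,
)
from bayesgrowth.synthetic_experiments import SimSpec, generate_curve
from conftest import random_valid_params

LOG_SQRT_2PI = 0.5 * math.log(2 * math.pi)


def _flat_params(level: float) -> GrowthParams:
    """Parameters whose prediction is essentially constant at ``level``."""
    return GrowthParams(y0=level, mu_max=1e-6, h0=0.0, ymax=level + 1e3)


def _curve_with_residuals(residuals, censored=None, threshold=None):
    n = len(residuals)
    times = np.arange(n, dtype=float)
    values = 3.0 + np.asarray(residuals, dtype=float)
    return GrowthCurve(times, values, censored, threshold)


class TestGaussian:
    def test_zero_residuals(self):
        curve = _curve_with_residuals([0.0] * 5)
        assert gaussian_loglik(curve, _flat_params(3.0), 1.0) == pytest.approx(
            -5 * LOG_SQRT_2PI, abs=1e-6
        )

    def test_single_residual_values(self):
        curve = _curve_with_residuals([2.0, 0.0])
        # 2 points: one residual 2, one residual 0, sigma=1
        expected = -2 * LOG_SQRT_2PI - 2.0
        assert gaussian_loglik(curve, _flat_params(3.0), 1.0) == pytest.approx(expected, abs=1e-6)

    def test_sigma_scaling(self):
        curve = _curve_with_residuals([0.0, 0.0])
        expected = 2 * -math.log(0.5 * math.sqrt(2 * math.pi))
        assert gaussian_loglik(curve, _flat_params(3.0), 0.5) == pytest.approx(expected, abs=1e-6)

    def test_maximised_at_rms_residual(self, rng):
        residuals = rng.normal(0, 0.3, 40)
        curve = _curve_with_residuals(residuals)
        p = _flat_params(3.0)
        sigma_hat = math.sqrt(np.mean(residuals**2))
        best = gaussian_loglik(curve, p, sigma_hat)
        for sigma in [0.5 * sigma_hat, 0.9 * sigma_hat, 1.1 * sigma_hat, 2 * sigma_hat]:
            assert gaussian_loglik(curve, p, sigma) < best

    def test_invalid_inputs(self):
        curve = _curve_with_residuals([0.0, 0.0])
        with pytest.raises(ValueError):
            gaussian_loglik(curve, _flat_params(3.0), 0.0)
        cens = _curve_with_residuals([0.0, -2.5], censored=[False, True], threshold=0.7)
        with pytest.raises(ValueError):
            gaussian_loglik(cens, _flat_params(3.0), 1.0)


class TestCensoredPoint:
    def test_below_threshold_is_uniform_density(self):
        assert censored_point_loglik(0.4, 1.3, 0.1) == pytest.approx(-0.2623642644674911, abs=1e-9)

    def test_continuous_at_threshold(self):
        at = censored_point_loglik(1.3, 1.3, 0.1)
        just_below = censored_point_loglik(1.3 - 1e-9, 1.3, 0.1)
        just_above = censored_point_loglik(1.3 + 1e-9, 1.3, 0.1)
        assert at == pytest.approx(math.log(1 / 1.3), abs=1e-12)
        assert just_below == pytest.approx(at, abs=1e-9)
        assert just_above == pytest.approx(at, abs=1e-9)

    def test_gaussian_tail_penalty(self):
        expected = math.log(1 / 1.3) - 2.0  # (0.2)^2 / (2 * 0.01)
        assert censored_point_loglik(1.5, 1.3, 0.1) == pytest.approx(expected, abs=1e-9)

    def test_non_increasing_above_threshold(self):
        values = [censored_point_loglik(x, 1.3, 0.05) for x in np.linspace(0, 3, 100)]
        assert np.all(np.diff(values) <= 1e-12)

    def test_conventional_thresholds_available(self):
        assert DETECTION_THRESHOLDS == (0.7, 1.3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            censored_point_loglik(0.5, -1.0, 0.1)
        with pytest.raises(ValueError):
            censored_point_loglik(0.5, 1.3, 0.0)


class TestCurveAndJoint:
    def test_uncensored_curve_equals_gaussian(self, rng):
        curve = _curve_with_residuals(rng.normal(0, 0.2, 8))
        p = _flat_params(3.0)
        assert curve_loglik(curve, p, 0.7) == pytest.approx(gaussian_loglik(curve, p, 0.7))

    def test_all_censored_below_threshold(self):
        curve = _curve_with_residuals([-2.5] * 4, censored=[True] * 4, threshold=1.3)
        p = _flat_params(0.2)  # model stays below threshold
        assert curve_loglik(curve, p, 1.0) == pytest.approx(4 * math.log(1 / 1.3), abs=1e-9)

    def test_mixed_curve(self):
        curve = GrowthCurve(
            times=[0.0, 1.0, 2.0, 3.0],
            values=[0.5, 3.0, 3.0, 3.0],
            censored=[True, False, False, False],
            threshold=1.3,
        )
        p = _flat_params(3.0)  # residual 0 at uncensored points, above threshold at censored
        # the censored point's prediction (3.0) is above the threshold: tail applies
        expected = -3 * LOG_SQRT_2PI + math.log(1 / 1.3) - (3.0 - 1.3) ** 2 / (2 * 0.05**2)
        assert curve_loglik(curve, p, 1.0, tail_sd=0.05) == pytest.approx(expected, rel=1e-6)

    def test_mixed_curve_model_below_threshold(self):
        curve = GrowthCurve(
            times=[0.0, 1.0, 2.0, 3.0],
            values=[0.2, 0.2, 0.2, 0.2],
            censored=[True, False, False, False],
            threshold=1.3,
        )
        p = _flat_params(0.2)
        expected = -3 * LOG_SQRT_2PI + math.log(1 / 1.3)
        assert curve_loglik(curve, p, 1.0) == pytest.approx(expected, abs=1e-6)

    def test_joint_additivity_and_symmetry(self, rng):
        c1 = _curve_with_residuals(rng.normal(0, 0.2, 4))
        c2 = _curve_with_residuals(rng.normal(0, 0.2, 4))
        p = _flat_params(3.0)
        ab = joint_loglik(c1, c2, p, p, 0.8)
        ba = joint_loglik(c2, c1, p, p, 0.8)
        assert ab == pytest.approx(ba, abs=1e-12)
        assert ab == pytest.approx(curve_loglik(c1, p, 0.8) + curve_loglik(c2, p, 0.8))

    def test_joint_perfect_fit_value(self):
        c = _curve_with_residuals([0.0] * 4)
        p = _flat_params(3.0)
        assert joint_loglik(c, c, p, p, 1.0) == pytest.approx(-8 * LOG_SQRT_2PI, abs=1e-6)

    def test_per_curve_sigma_option(self):
        c = _curve_with_residuals([0.0] * 4)
        p = _flat_params(3.0)
        two = joint_loglik(c, c, p, p, (1.0, 0.5))
        assert two == pytest.approx(curve_loglik(c, p, 1.0) + curve_loglik(c, p, 0.5))

    def test_loglik_decreases_with_growing_residual(self):
        p = _flat_params(3.0)
        values = []
        for r in [0.0, 0.5, 1.0, 2.0, 4.0]:
            curve = _curve_with_residuals([r, 0.0, 0.0])
            values.append(curve_loglik(curve, p, 0.5))
        assert np.all(np.diff(values) < 0)


class TestFastKernel:
    def test_matches_public_implementation(self, rng):
        """Sampler kernel and validated API agree on random inputs."""
        curve = generate_curve(SimSpec(sigma=0.2, seed=11, threshold=4.0))
        assert curve.n_censored > 0
        kernel = make_curve_loglik(curve, tail_sd=0.05)
        for _ in range(50):
            p = random_valid_params(rng)
            sigma = rng.uniform(0.05, 1.0)
            fast = kernel(p.y0, p.mu_max, p.h0, p.ymax, sigma)
            slow = curve_loglik(curve, p, sigma, tail_sd=0.05)
            assert fast == pytest.approx(slow, rel=1e-10, abs=1e-8)

    def test_off_support_returns_neg_inf(self):
        curve = generate_curve(SimSpec(sigma=0.1, seed=1))
        kernel = make_curve_loglik(curve)
        assert kernel(5.0, 0.1, 1.0, 4.0, 0.1) == -np.inf  # ymax <= y0
        assert kernel(3.0, -0.1, 1.0, 9.0, 0.1) == -np.inf
        assert kernel(3.0, 0.1, 1.0, 9.0, -0.5) == -np.inf


class TestValidation:
    def test_curve_invariants(self):
        with pytest.raises(ValueError):
            GrowthCurve([0.0, 0.0], [1.0, 2.0])  # non-increasing times
        with pytest.raises(ValueError):
            GrowthCurve([0.0], [1.0])  # too short
        with pytest.raises(ValueError):
            GrowthCurve([0.0, 1.0], [1.0, 2.0], [True, False])  # censored, no threshold
        with pytest.raises(ValueError):
            GrowthCurve([0.0, 1.0], [2.0, 3.0], [True, False], threshold=1.3)

    def test_noise_spec(self):
        with pytest.raises(ValueError):
            NoiseSpec(mode="fixed")
        with pytest.raises(ValueError):
            NoiseSpec(mode="other")
        with pytest.raises(ValueError):
            NoiseSpec(bounds=(1.0, 0.5))
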