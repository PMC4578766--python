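"""Nested-sampling evidence, constrained draws and posterior summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from bayesgrowth.nested_sampler import (
    NSConfig,
    NSResult,
    NestedSamplingError,
    constrained_draw,
    posterior_summary,
    run,
    staircase_sample,
)
from bayesgrowth.priors import PriorEntry, PriorSpec

SPEC_1D = PriorSpec({"x": PriorEntry("uniform", -10, 10)})
SPEC_2D = PriorSpec(
    {"x": PriorEntry("uniform", -10, 10), "y": PriorEntry("uniform", -10, 10)}
)


def gauss1d(theta):
    return -0.5 * theta[0] ** 2 - 0.5 * math.log(2 * math.pi)


def gauss2d(theta):
    return -0.5 * (theta[0] ** 2 + theta[1] ** 2) - math.log(2 * math.pi)


class TestEvidence:
    def test_constant_likelihood_integrates_exactly(self):
        c = -3.7
        res = run(lambda th: c, SPEC_1D, NSConfig(n_live=50, seed=0))
        assert res.log_evidence == pytest.approx(c, abs=1e-9)

    def test_1d_gaussian_toy(self):
        res = run(gauss1d, SPEC_1D, NSConfig(n_live=200, seed=3))
        assert res.log_evidence == pytest.approx(math.log(1 / 20), abs=3 * res.log_evidence_sd)

    def test_2d_gaussian_toy(self):
        res = run(gauss2d, SPEC_2D, NSConfig(n_live=200, seed=3))
        assert res.log_evidence == pytest.approx(2 * math.log(1 / 20), abs=3 * res.log_evidence_sd)

    def test_seeded_run_is_reproducible(self):
        a = run(gauss1d, SPEC_1D, NSConfig(n_live=60, seed=9))
        b = run(gauss1d, SPEC_1D, NSConfig(n_live=60, seed=9))
        assert a.log_evidence == b.log_evidence
        assert np.array_equal(a.samples, b.samples)

    def test_posterior_matches_analytic_gaussian(self):
        res = run(gauss1d, SPEC_1D, NSConfig(n_live=300, seed=4))
        mean, sd = posterior_summary(res, 0)
        assert mean == pytest.approx(0.0, abs=0.15)
        assert sd == pytest.approx(1.0, abs=0.12)

    def test_reported_uncertainty_calibrated(self):
        """Empirical lnZ scatter agrees with sqrt(H/n) within a factor 2."""
        estimates, reported = [], []
        for seed in range(50):
            res = run(gauss1d, SPEC_1D, NSConfig(n_live=100, seed=seed))
            estimates.append(res.log_evidence)
            reported.append(res.log_evidence_sd)
        empirical = np.std(estimates, ddof=1)
        assert np.mean(reported) / 2 < empirical < np.mean(reported) * 2

    def test_sd_shrinks_with_root_n_live(self):
        lo = [run(gauss1d, SPEC_1D, NSConfig(n_live=50, seed=s)).log_evidence for s in range(20)]
        hi = [run(gauss1d, SPEC_1D, NSConfig(n_live=100, seed=s)).log_evidence for s in range(20)]
        ratio = np.std(lo, ddof=1) / np.std(hi, ddof=1)
        assert math.sqrt(2) / 1.5 < ratio < math.sqrt(2) * 1.5

    def test_dead_points_have_non_decreasing_likelihood(self):
        res = run(gauss1d, SPEC_1D, NSConfig(n_live=80, seed=2))
        dead = res.log_likelihoods[: res.n_iterations]
        assert np.all(np.diff(dead) >= 0)

    def test_shrinkage_bookkeeping(self):
        res = run(gauss1d, SPEC_1D, NSConfig(n_live=80, seed=2))
        assert np.exp(res.log_widths).sum() == pytest.approx(1.0, abs=1e-9)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(res.weights >= 0)

    def test_all_dead_initialisation_fails(self):
        with pytest.raises(NestedSamplingError):
            run(lambda th: -np.inf, SPEC_1D, NSConfig(n_live=20, seed=0))

    def test_iteration_cap_flags_result(self):
        with pytest.warns(RuntimeWarning):
            res = run(gauss1d, SPEC_1D, NSConfig(n_live=100, seed=0, max_iterations=50))
        assert res.flagged

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            NSConfig(n_live=1)
        with pytest.raises(ValueError):
            NSConfig(termination_tolerance=2.0)


class TestConstrainedDraw:
    def _live(self, rng, loglik, spec, n=40):
        u = rng.random((n, len(spec)))
        l = np.array([loglik(spec.transform(ui)) for ui in u])
        return u, l

    def test_respects_likelihood_constraint(self, rng):
        cfg = NSConfig(n_live=40, seed=0)
        u, l = self._live(rng, gauss1d, SPEC_1D)
        l_star = np.median(l)
        for _ in range(20):
            unew, lnew, _ = constrained_draw(u, l, l_star, gauss1d, SPEC_1D, cfg, rng)
            assert lnew > l_star

    def test_bitwise_reproducible(self):
        cfg = NSConfig(n_live=40, seed=0)
        rng = np.random.default_rng(5)
        u, l = self._live(rng, gauss1d, SPEC_1D)
        l_star = float(np.min(l))
        draws = []
        for seed in (123, 123):
            unew, lnew, _ = constrained_draw(
                u, l, l_star, gauss1d, SPEC_1D, cfg, np.random.default_rng(seed)
            )
            draws.append((unew.copy(), lnew))
        assert np.array_equal(draws[0][0], draws[1][0])
        assert draws[0][1] == draws[1][1]

    def test_flat_likelihood_samples_the_prior(self, rng):
        """With no constraint the walk must leave the prior invariant."""
        cfg = NSConfig(n_live=40, seed=0, max_mcmc_steps=20)
        flat = lambda th: 0.0
        u, l = self._live(rng, flat, SPEC_1D)
        xs = np.empty(10_000)
        for i in range(xs.size):
            unew, _, _ = constrained_draw(u, l, -1.0, flat, SPEC_1D, cfg, rng, step_scale=2.0)
            xs[i] = SPEC_1D.transform(unew)[0]
        # against the uniform(-10, 10) prior
        assert stats.kstest(xs, stats.uniform(loc=-10, scale=20).cdf).pvalue > 0.01


class TestSummaries:
    def _result(self, samples, weights):
        samples = np.asarray(samples, dtype=float).reshape(len(samples), -1)
        weights = np.asarray(weights, dtype=float)
        return NSResult(
            log_evidence=0.0,
            log_evidence_sd=0.0,
            samples=samples,
            log_likelihoods=np.zeros(len(weights)),
            log_widths=np.log(np.maximum(weights, 1e-300)),
            weights=weights,
            information_H=0.0,
            n_iterations=len(weights),
            n_calls=0,
            param_names=("p",),
        )

    def test_degenerate_single_sample(self):
        assert posterior_summary(self._result([3.2], [1.0]), 0) == (3.2, 0.0)

    def test_two_equal_weights(self):
        mean, sd = posterior_summary(self._result([0.0, 2.0], [0.5, 0.5]), 0)
        assert (mean, sd) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_weighted_hand_example(self):
        mean, sd = posterior_summary(self._result([0.0, 4.0], [0.75, 0.25]), 0)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(math.sqrt(3.0))

    def test_staircase_degenerate(self, rng):
        res = self._result([0.0, 7.0], [0.0, 1.0])
        draws = staircase_sample(res, 50, rng)
        assert np.all(draws == 7.0)

    def test_staircase_frequencies_binomial(self, rng):
        res = self._result([0.0, 1.0], [0.5, 0.5])
        draws = staircase_sample(res, 10_000, rng)
        count = int(draws.sum())
        band = stats.binom.interval(0.99, 10_000, 0.5)
        assert band[0] <= count <= band[1]

    def test_staircase_reproducible_and_validated(self):
        res = self._result([0.0, 1.0], [0.5, 0.5])
        a = staircase_sample(res, 100, np.random.default_rng(1))
        b = staircase_sample(res, 100, np.random.default_rng(1))
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            staircase_sample(res, 0)

    def test_staircase_mean_matches_weighted_summary(self):
        rng = np.random.default_rng(0)
        w = rng.random(20)
        w /= w.sum()
        res = self._result(rng.normal(size=20), w)
        mean, sd = posterior_summary(res, 0)
        draws = staircase_sample(res, 10_000, np.random.default_rng(2))
        se = sd / math.sqrt(10_000)
        assert abs(draws.mean() - mean) < max(3 * se, 0.05 * sd + 1e-12)
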