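"""Hypothesis scoring, Bayes factors and the F-test baseline."""

import math
from dataclasses import replace

import numpy as np
import pytest

from bayesgrowth.comparison import (
    BayesComparisonResult,
    compare_pair,
    f_statistic,
    f_test,
    fit_least_squares,
    jeffreys_category,
)
from bayesgrowth.growth_model import GrowthParams
from bayesgrowth.nested_sampler import NSConfig
from bayesgrowth.synthetic_experiments import DEFAULT_BASE_PARAMS, SimSpec, generate_curve

CFG = NSConfig(n_live=100, seed=17)


@pytest.fixture(scope="module")
def easy_pair():
    """Clearly different growth rates (0.11 vs 0.22), low noise."""
    a = generate_curve(SimSpec(sigma=0.05, seed=21))
    b = generate_curve(
        SimSpec(params=replace(DEFAULT_BASE_PARAMS, mu_max=0.22), sigma=0.05, seed=22)
    )
    return a, b


@pytest.fixture(scope="module")
def easy_result(easy_pair):
    return compare_pair(*easy_pair, CFG)


class TestJeffreysScale:
    @pytest.mark.parametrize(
        "value, label",
        [
            (1.0, "hardly worth mentioning"),
            (3.0, "has some substance"),
            (7.0, "strong"),
            (12.0, "very strong"),
            (0.0, "hardly worth mentioning"),
        ],
    )
    def test_bands(self, value, label):
        assert jeffreys_category(value) == label

    def test_negative_values_reverse_direction(self):
        assert jeffreys_category(-7.0) == "strong (direction reversed)"

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            jeffreys_category(float("nan"))


class TestComparePair:
    def test_bayes_factor_additivity(self, easy_result):
        r = easy_result
        assert r.ln_bayes_factor(1, 2) + r.ln_bayes_factor(2, 3) == pytest.approx(
            r.ln_bayes_factor(1, 3), abs=1e-12
        )
        m = r.two_ln_b_matrix()
        assert m[0, 1] == pytest.approx(2 * r.ln_bayes_factor(1, 2))
        assert np.allclose(m, -m.T)

    def test_detects_clear_rate_difference(self, easy_result):
        assert 2 * easy_result.ln_bayes_factor(3, 2) > 2
        assert easy_result.rates_differ
        assert easy_result.verdict == "different growth rates"

    def test_verdict_invariant_under_swap(self, easy_pair):
        a, b = easy_pair
        swapped = compare_pair(b, a, CFG)
        assert swapped.rates_differ

    def test_identical_data_favours_replicate_hypothesis(self):
        c = generate_curve(SimSpec(sigma=0.05, seed=30))
        r = compare_pair(c, c, NSConfig(n_live=100, seed=3))
        assert r.ln_bayes_factor(1, 3) > 0  # Occam's razor
        assert not r.rates_differ

    def test_posterior_summaries_present(self, easy_result):
        for hyp, names in [
            ("H1", {"y0", "mu_max", "h0", "ymax", "sigma"}),
            ("H2", {"y0_A", "h0_A", "ymax_A", "y0_B", "h0_B", "ymax_B", "mu_max", "sigma"}),
            (
                "H3",
                {
                    "y0_A", "mu_max_A", "h0_A", "ymax_A",
                    "y0_B", "mu_max_B", "h0_B", "ymax_B", "sigma",
                },
            ),
        ]:
            assert set(easy_result.posterior[hyp]) == names
        # under H3 the two rate posteriors should straddle the truth
        mu_a = easy_result.posterior["H3"]["mu_max_A"][0]
        mu_b = easy_result.posterior["H3"]["mu_max_B"][0]
        assert abs(mu_a - 0.11) < 0.03
        assert abs(mu_b - 0.22) < 0.06

    def test_seeded_determinism(self, easy_pair):
        a, b = easy_pair
        r1 = compare_pair(a, b, NSConfig(n_live=50, seed=99))
        r2 = compare_pair(a, b, NSConfig(n_live=50, seed=99))
        assert r1.log_evidences == r2.log_evidences

    def test_unknown_mu_prior_key_rejected(self, easy_pair):
        with pytest.raises(ValueError):
            compare_pair(*easy_pair, CFG, mu_prior={"C": None})


class TestLeastSquares:
    def test_noise_free_recovery(self, clean_curve):
        fit = fit_least_squares([clean_curve], "separated", n_starts=10, seed=0)
        assert fit.ssr < 1e-8
        truth = DEFAULT_BASE_PARAMS
        p = fit.params[0]
        assert p.mu_max == pytest.approx(truth.mu_max, abs=1e-3)
        assert p.y0 == pytest.approx(truth.y0, abs=1e-3)
        assert p.ymax == pytest.approx(truth.ymax, abs=1e-3)
        assert p.h0 == pytest.approx(truth.h0, abs=2e-3)

    def test_identical_curves_unified_equals_separated(self, noisy_curve):
        sep = fit_least_squares([noisy_curve, noisy_curve], "separated", seed=1)
        uni = fit_least_squares([noisy_curve, noisy_curve], "unified", seed=1)
        assert uni.ssr == pytest.approx(sep.ssr, abs=1e-6)

    def test_unified_never_beats_separated(self):
        a = generate_curve(SimSpec(sigma=0.15, seed=41))
        b = generate_curve(
            SimSpec(params=replace(DEFAULT_BASE_PARAMS, mu_max=0.16), sigma=0.15, seed=42)
        )
        sep = fit_least_squares([a, b], "separated", seed=2)
        uni = fit_least_squares([a, b], "unified", seed=2)
        assert uni.ssr >= sep.ssr - 1e-9
        assert sep.n_params == 8 and uni.n_params == 7

    def test_too_few_points_rejected(self):
        from bayesgrowth.likelihood import GrowthCurve

        tiny = GrowthCurve([0.0, 1.0, 2.0], [3.0, 3.5, 4.0])
        with pytest.raises(ValueError):
            fit_least_squares([tiny], "separated")
        with pytest.raises(ValueError):
            fit_least_squares([tiny], "pooled")


class TestFTest:
    def test_hand_built_vectors(self):
        """Direct arithmetic: 8 points, unified-vs-separated sum 1, residual sum 2."""
        data = np.zeros(8)
        ys = np.concatenate([np.full(4, 0.5), np.zeros(4)])  # sum (d - ys)^2 = 1 ... scaled below
        # construct exactly: sum (d - ys)^2 = 2.0, sum (yu - ys)^2 = 1.0
        ys = np.full(8, 0.5)  # (d - ys)^2 = 0.25 each -> 2.0
        yu = ys + math.sqrt(1.0 / 8.0)  # (yu - ys)^2 = 1/8 each -> 1.0
        f, df1, df2 = f_statistic(data, ys, yu)
        assert f == pytest.approx(1.0 / (2.0 / 7.0))
        assert (df1, df2) == (1, 1)

    def test_degrees_of_freedom_rule(self):
        a = generate_curve(SimSpec(sigma=0.1, seed=51, n_points=16))
        b = generate_curve(SimSpec(sigma=0.1, seed=52, n_points=16))
        res = f_test(a, b, n_starts=5, seed=0)
        assert (res.df1, res.df2) == (1, 25)  # 8-7 and 32-7

    def test_identical_curves_give_null_result(self, noisy_curve):
        res = f_test(noisy_curve, noisy_curve, n_starts=6, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-2)
        assert res.p_value > 0.9
        assert not res.reject_null
        assert res.verdict == "same growth rate"

    def test_detects_large_rate_difference(self):
        a = generate_curve(SimSpec(sigma=0.05, seed=61))
        b = generate_curve(
            SimSpec(params=replace(DEFAULT_BASE_PARAMS, mu_max=0.22), sigma=0.05, seed=62)
        )
        res = f_test(a, b, seed=0)
        assert res.reject_null and res.p_value < 0.001

    def test_perfect_fit_is_degenerate(self, clean_curve):
        res = f_test(clean_curve, clean_curve, n_starts=6, seed=0)
        assert res.degenerate
        assert res.p_value == 0.0
        assert math.isinf(res.statistic)

    def test_conventional_variant(self):
        data = np.zeros(8)
        ys = np.full(8, 0.5)
        yu = np.full(8, 0.6)
        f_conv, df1, df2 = f_statistic(data, ys, yu, conventional=True)
        ssr_s, ssr_u = 2.0, float(np.sum((data - yu) ** 2))
        assert f_conv == pytest.approx(((ssr_u - ssr_s) / 1) / (ssr_s / 1))
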