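"""Comparing growth rates between two curves.

Three hypotheses describe a pair of curves:

- **H1** — the curves are replicates: one parameter set serves both.
- **H2** — the curves share the growth rate ``mu_max`` but differ in
  ``y0``, ``h0`` and ``ymax``.
- **H3** — the curves share no parameters.

Each hypothesis's evidence is computed by nested sampling of the combined
two-curve likelihood; assuming equal prior probabilities the hypotheses are
then ranked by Bayes factors ``B_ij = Z_i / Z_j``, read on Jeffreys' scale
for ``2 ln B``:

====== =============================
0 - 2  hardly worth mentioning
2 - 6  has some substance
6 - 10 strong
> 10   very strong
====== =============================

Growth rates are declared *different* when there is at least substantial
evidence for H3 over H2, i.e. ``2 ln B32 >= 2``.

The frequentist baseline is an F-test contrasting a *separated* fit (two
independent four-parameter fits, 8 parameters) against a *unified* fit
(shared growth rate, 7 parameters), with

    F = sum_i (y_i^u - y_i^s)^2 / [ sum_i (d_i - y_i^s)^2 / (N1 + N2 - 1) ]

df1 = 1 and df2 = N1 + N2 - 7; the null (equal rates) is rejected at
p < 0.05. The ``(N1 + N2 - 1)`` divisor is kept as such deliberately; pass
``conventional=True`` for the textbook extra-sum-of-squares statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize, stats

from .growth_model import GrowthParams
from .likelihood import DEFAULT_TAIL_SD, GrowthCurve, NoiseSpec
from .nested_sampler import NSConfig, NSResult, NestedSamplingError, run
from .priors import MU_EPSILON, PriorEntry, PriorSpec, default_bounds

__all__ = [
    "HYPOTHESES",
    "BayesComparisonResult",
    "FTestResult",
    "LeastSquaresFit",
    "compare_pair",
    "jeffreys_category",
    "fit_least_squares",
    "f_statistic",
    "f_test",
    "decision_threshold",
]

HYPOTHESES = ("H1", "H2", "H3")

#: "Substantial evidence" decision threshold on 2 ln B32.
decision_threshold = 2.0

_JEFFREYS_BANDS = (
    (2.0, "hardly worth mentioning"),
    (6.0, "has some substance"),
    (10.0, "strong"),
    (math.inf, "very strong"),
)


def jeffreys_category(two_ln_b: float) -> str:
    """Jeffreys'-scale label for a value of ``2 ln B``.

    Negative values are categorised by magnitude — evidence for the other
    hypothesis — and flagged with ``(direction reversed)``.
    """
    if np.isnan(two_ln_b):
        raise ValueError("2 ln B must not be NaN")
    mag = abs(float(two_ln_b))
    for limit, label in _JEFFREYS_BANDS:
        if mag < limit:
            break
    if two_ln_b < 0:
        return f"{label} (direction reversed)"
    return label


def _union_entry(a: PriorEntry, b: PriorEntry) -> PriorEntry:
    """Uniform entry spanning both curves' data-scaled bounds."""
    return PriorEntry("uniform", min(a.lower, b.lower), max(a.upper, b.upper))


@dataclass
class BayesComparisonResult:
    """Evidences, Bayes factors and summaries for the three hypotheses."""

    log_evidences: Dict[str, float]
    log_evidence_sds: Dict[str, float]
    posterior: Dict[str, Dict[str, Tuple[float, float]]]
    results: Dict[str, NSResult]

    def ln_bayes_factor(self, i: int, j: int) -> float:
        """``ln B_ij = ln Z_i - ln Z_j`` for hypothesis numbers 1..3."""
        return self.log_evidences[f"H{i}"] - self.log_evidences[f"H{j}"]

    def two_ln_b_matrix(self) -> np.ndarray:
        z = np.array([self.log_evidences[h] for h in HYPOTHESES])
        return 2.0 * (z[:, None] - z[None, :])

    def categories(self) -> Dict[str, str]:
        return {
            f"2lnB{i}{j}": jeffreys_category(2.0 * self.ln_bayes_factor(i, j))
            for i, j in ((1, 2), (1, 3), (2, 3))
        }

    @property
    def rates_differ(self) -> bool:
        """Substantial-evidence rule: 2 ln B32 >= 2."""
        return 2.0 * self.ln_bayes_factor(3, 2) >= decision_threshold

    @property
    def verdict(self) -> str:
        return "different growth rates" if self.rates_differ else "same growth rate"


def _hypothesis_layouts(
    spec_a: PriorSpec,
    spec_b: PriorSpec,
    noise: NoiseSpec,
    mu_priors: Dict[str, Optional[PriorEntry]],
):
    """Prior spec plus (index-map) tying structure for each hypothesis.

    Returns ``{hyp: (PriorSpec, idx_a, idx_b, sigma_idx)}`` where ``idx_*``
    give positions of (y0, mu_max, h0, ymax) for each curve in the joint
    parameter vector.
    """
    infer_sigma = noise.mode == "inferred"
    mu_union = _union_entry(spec_a["mu_max"], spec_b["mu_max"])
    mu_shared = mu_priors.get("shared") or mu_union
    mu_a = mu_priors.get("A") or spec_a["mu_max"]
    mu_b = mu_priors.get("B") or spec_b["mu_max"]
    sigma_entry = None
    if infer_sigma:
        sigma_entry = _union_entry(spec_a["sigma"], spec_b["sigma"])
        sigma_entry = PriorEntry("jeffreys", sigma_entry.lower, sigma_entry.upper)

    layouts = {}

    h1 = {
        "y0": _union_entry(spec_a["y0"], spec_b["y0"]),
        "mu_max": mu_shared,
        "h0": _union_entry(spec_a["h0"], spec_b["h0"]),
        "ymax": _union_entry(spec_a["ymax"], spec_b["ymax"]),
    }
    if infer_sigma:
        h1["sigma"] = sigma_entry
    layouts["H1"] = (PriorSpec(h1), (0, 1, 2, 3), (0, 1, 2, 3), 4 if infer_sigma else None)

    h2 = {
        "y0_A": spec_a["y0"],
        "h0_A": spec_a["h0"],
        "ymax_A": spec_a["ymax"],
        "y0_B": spec_b["y0"],
        "h0_B": spec_b["h0"],
        "ymax_B": spec_b["ymax"],
        "mu_max": mu_shared,
    }
    if infer_sigma:
        h2["sigma"] = sigma_entry
    layouts["H2"] = (
        PriorSpec(h2, joint_ymax_gt_y0=False),
        (0, 6, 1, 2),
        (3, 6, 4, 5),
        7 if infer_sigma else None,
    )

    h3 = {
        "y0_A": spec_a["y0"],
        "mu_max_A": mu_a,
        "h0_A": spec_a["h0"],
        "ymax_A": spec_a["ymax"],
        "y0_B": spec_b["y0"],
        "mu_max_B": mu_b,
        "h0_B": spec_b["h0"],
        "ymax_B": spec_b["ymax"],
    }
    if infer_sigma:
        h3["sigma"] = sigma_entry
    layouts["H3"] = (
        PriorSpec(h3, joint_ymax_gt_y0=False),
        (0, 1, 2, 3),
        (4, 5, 6, 7),
        8 if infer_sigma else None,
    )
    return layouts


def compare_pair(
    curve_a: GrowthCurve,
    curve_b: GrowthCurve,
    config: Optional[NSConfig] = None,
    noise: Optional[NoiseSpec] = None,
    mu_prior: Union[None, PriorEntry, Mapping[str, PriorEntry]] = None,
    tail_sd: float = DEFAULT_TAIL_SD,
) -> BayesComparisonResult:
    """Score H1/H2/H3 for a pair of curves by nested-sampling evidence.

    ``mu_prior`` optionally injects informative growth-rate priors: a single
    :class:`PriorEntry` applies everywhere, or a mapping with keys ``"A"``,
    ``"B"`` (per-curve priors under H3) and ``"shared"`` (H1/H2). Per-curve
    nuisance parameters always use each curve's own data-scaled bounds.

    The noise level is shared between the two curves within each hypothesis
    (inferred under a Jeffreys prior by default). Deterministic given
    ``config.seed``; the three hypothesis runs use independent child
    generators spawned from it.
    """
    config = config or NSConfig()
    noise = noise or NoiseSpec()
    if mu_prior is None:
        mu_priors: Dict[str, Optional[PriorEntry]] = {}
    elif isinstance(mu_prior, PriorEntry):
        mu_priors = {"A": mu_prior, "B": mu_prior, "shared": mu_prior}
    else:
        unknown = set(mu_prior) - {"A", "B", "shared"}
        if unknown:
            raise ValueError(f"unknown mu_prior keys: {sorted(unknown)}")
        mu_priors = dict(mu_prior)

    from functools import partial

    from ._kernels import pair_loglik_kernel

    spec_a = default_bounds(curve_a, noise)
    spec_b = default_bounds(curve_b, noise)
    layouts = _hypothesis_layouts(spec_a, spec_b, noise, mu_priors)
    sigma_fixed = float(noise.sigma_fixed) if noise.sigma_fixed is not None else 0.0
    inv_tail2 = 0.5 / (tail_sd * tail_sd)
    static = []
    for curve in (curve_a, curve_b):
        static += [
            np.ascontiguousarray(curve.times, dtype=float),
            np.ascontiguousarray(curve.values, dtype=float),
            np.ascontiguousarray(curve.censored, dtype=bool),
            float(curve.threshold) if curve.threshold is not None else 1.0,
        ]

    seeds = np.random.SeedSequence(config.seed).spawn(len(HYPOTHESES))
    log_z: Dict[str, float] = {}
    log_z_sd: Dict[str, float] = {}
    posterior: Dict[str, Dict[str, Tuple[float, float]]] = {}
    results: Dict[str, NSResult] = {}
    for hyp, seed_seq in zip(HYPOTHESES, seeds):
        spec, ia, ib, isig = layouts[hyp]
        idx = np.array(list(ia) + list(ib), dtype=np.int64)
        loglik = partial(
            pair_loglik_kernel,
            *static,
            inv_tail2,
            idx,
            isig if isig is not None else -1,
            sigma_fixed,
        )

        try:
            res = run(loglik, spec, config, rng=np.random.default_rng(seed_seq))
        except NestedSamplingError as exc:
            raise NestedSamplingError(f"{hyp}: {exc}") from exc
        results[hyp] = res
        log_z[hyp] = res.log_evidence
        log_z_sd[hyp] = res.log_evidence_sd
        posterior[hyp] = {name: res.summary(name) for name in spec.names}
    return BayesComparisonResult(log_z, log_z_sd, posterior, results)


# ---------------------------------------------------------------------------
# Frequentist baseline
# ---------------------------------------------------------------------------


@dataclass
class LeastSquaresFit:
    """Best multistart least-squares fit of one or two curves."""

    params: List[GrowthParams]
    fitted: List[np.ndarray]
    ssr: float
    n_params: int


@dataclass
class FTestResult:
    """F-test of equal growth rates between two curves."""

    statistic: float
    df1: int
    df2: int
    p_value: float
    reject_null: bool
    separated: LeastSquaresFit
    unified: LeastSquaresFit
    degenerate: bool = False
    threshold: float = 0.05

    @property
    def verdict(self) -> str:
        return "different growth rates" if self.reject_null else "same growth rate"


def _fit_bounds(curve: GrowthCurve) -> Tuple[np.ndarray, np.ndarray]:
    """Optimizer box for (y0, mu_max, h0, g=ymax-y0); g>0 encodes ymax>y0."""
    spec = default_bounds(curve, NoiseSpec(mode="fixed", sigma_fixed=1.0))
    lo = np.array([spec["y0"].lower, MU_EPSILON, 0.0, 1e-6])
    hi = np.array(
        [
            spec["y0"].upper,
            spec["mu_max"].upper,
            spec["h0"].upper,
            spec["ymax"].upper - spec["y0"].lower,
        ]
    )
    return lo, hi


def _heuristic_start(curve: GrowthCurve, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    d, t = curve.values, curve.times
    slopes = np.diff(d) / np.diff(t)
    mu = float(np.clip(np.max(slopes), lo[1] * 2, hi[1] * 0.9)) if slopes.size else lo[1] * 2
    start = np.array([d.min(), mu, min(1.0, hi[2] / 2), max(d.max() - d.min(), 0.5)])
    return np.clip(start, lo, hi)


def _to_params(x: np.ndarray) -> GrowthParams:
    return GrowthParams(y0=x[0], mu_max=x[1], h0=x[2], ymax=x[0] + x[3])


def fit_least_squares(
    curves: Sequence[GrowthCurve],
    tying: str = "separated",
    n_starts: int = 10,
    seed: int = 0,
) -> LeastSquaresFit:
    """Least-squares Baranyi–Roberts fit(s) on the log10 scale.

    ``separated`` fits each curve independently (4 parameters per curve);
    ``unified`` fits all curves jointly with a single shared growth rate
    (``4 * n_curves - (n_curves - 1)`` parameters). Each optimisation takes
    the best of ``n_starts`` seeded multistart runs (one heuristic start,
    the rest drawn uniformly inside the data-scaled box).
    """
    from .growth_model import predict_log10

    if tying not in ("separated", "unified"):
        raise ValueError("tying must be 'separated' or 'unified'")
    if n_starts < 1:
        raise ValueError("n_starts must be positive")
    curves = list(curves)
    n_total = sum(len(c) for c in curves)
    n_params = 4 * len(curves) if tying == "separated" else 3 * len(curves) + 1
    if n_total < n_params:
        raise ValueError("fewer data points than parameters")
    rng = np.random.default_rng(seed)

    if tying == "separated":
        fits, fitted, ssr = [], [], 0.0
        for curve in curves:
            best = _fit_single(curve, n_starts, rng)
            fits.append(_to_params(best.x))
            pred = predict_log10(curve.times, fits[-1])
            fitted.append(np.asarray(pred))
            ssr += float(np.sum((curve.values - pred) ** 2))
        return LeastSquaresFit(fits, fitted, ssr, n_params)

    # unified: theta = [mu] + per-curve (y0, h0, g)
    boxes = [_fit_bounds(c) for c in curves]
    lo = np.concatenate([[min(b[0][1] for b in boxes)]] + [b[0][[0, 2, 3]] for b in boxes])
    hi = np.concatenate([[max(b[1][1] for b in boxes)]] + [b[1][[0, 2, 3]] for b in boxes])

    def unpack(theta):
        out = []
        for i in range(len(curves)):
            y0, h0, g = theta[1 + 3 * i : 4 + 3 * i]
            out.append(np.array([y0, theta[0], h0, g]))
        return out

    def residuals(theta):
        res = []
        for curve, x in zip(curves, unpack(theta)):
            res.append(curve.values - predict_log10(curve.times, _to_params(x)))
        return np.concatenate(res)

    best = None
    for i in range(n_starts):
        if i == 0:
            start = np.concatenate(
                [[np.mean([_heuristic_start(c, *b)[1] for c, b in zip(curves, boxes)])]]
                + [_heuristic_start(c, *b)[[0, 2, 3]] for c, b in zip(curves, boxes)]
            )
        else:
            start = lo + rng.random(lo.size) * (hi - lo)
        start = np.clip(start, lo, hi)
        try:
            sol = optimize.least_squares(residuals, start, bounds=(lo, hi))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("least-squares fit failed for every start")
    params = [_to_params(x) for x in unpack(best.x)]
    fitted = [np.asarray(predict_log10(c.times, p)) for c, p in zip(curves, params)]
    ssr = float(sum(np.sum((c.values - f) ** 2) for c, f in zip(curves, fitted)))
    return LeastSquaresFit(params, fitted, ssr, n_params)


def _fit_single(curve: GrowthCurve, n_starts: int, rng: np.random.Generator):
    from .growth_model import predict_log10

    lo, hi = _fit_bounds(curve)

    def residuals(x):
        return curve.values - predict_log10(curve.times, _to_params(x))

    best = None
    for i in range(n_starts):
        start = (
            _heuristic_start(curve, lo, hi)
            if i == 0
            else lo + rng.random(4) * (hi - lo)
        )
        try:
            sol = optimize.least_squares(residuals, start, bounds=(lo, hi))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("least-squares fit failed for every start")
    return best


def f_statistic(
    data: np.ndarray,
    fitted_separated: np.ndarray,
    fitted_unified: np.ndarray,
    n_params_separated: int = 8,
    n_params_unified: int = 7,
    conventional: bool = False,
) -> Tuple[float, int, int]:
    """F statistic and degrees of freedom from observed and fitted vectors.

    Default form: numerator ``sum (y_u - y_s)^2``, denominator
    ``sum (d - y_s)^2 / (N - 1)`` with ``N`` the pooled point count;
    df1 is the parameter-count difference, df2 is ``N - n_params_unified``.
    Returns ``(F, df1, df2)``; ``F = inf`` when the separated fit is perfect.
    """
    data = np.asarray(data, dtype=float)
    ys = np.asarray(fitted_separated, dtype=float)
    yu = np.asarray(fitted_unified, dtype=float)
    n = data.size
    df1 = n_params_separated - n_params_unified
    df2 = n - n_params_unified
    denom_ss = float(np.sum((data - ys) ** 2))
    if denom_ss <= 1e-12:  # numerically perfect separated fit
        return math.inf, df1, df2
    if conventional:
        ssr_s = denom_ss
        ssr_u = float(np.sum((data - yu) ** 2))
        return (max(ssr_u - ssr_s, 0.0) / df1) / (ssr_s / df2), df1, df2
    numerator = float(np.sum((yu - ys) ** 2))
    return numerator / (denom_ss / (n - 1)), df1, df2


def f_test(
    curve_a: GrowthCurve,
    curve_b: GrowthCurve,
    n_starts: int = 10,
    seed: int = 0,
    threshold: float = 0.05,
    conventional: bool = False,
) -> FTestResult:
    """F-test of the null *the two curves have the same growth rate*.

    Compares the separated (8-parameter) and unified (7-parameter,
    shared-rate) fits. ``conventional=True`` replaces the statistic with the
    standard extra-sum-of-squares form
    ``[(SSR_u - SSR_s)/df1] / [SSR_s/df2]``.
    """
    separated = fit_least_squares([curve_a, curve_b], "separated", n_starts, seed)
    unified = fit_least_squares([curve_a, curve_b], "unified", n_starts, seed)
    data = np.concatenate([curve_a.values, curve_b.values])
    ys = np.concatenate(separated.fitted)
    yu = np.concatenate(unified.fitted)
    statistic, df1, df2 = f_statistic(
        data, ys, yu, separated.n_params, unified.n_params, conventional
    )
    degenerate = math.isinf(statistic)
    p_value = 0.0 if degenerate else float(stats.f.sf(statistic, df1, df2))
    return FTestResult(
        statistic=statistic,
        df1=df1,
        df2=df2,
        p_value=p_value,
        reject_null=p_value < threshold,
        separated=separated,
        unified=unified,
        degenerate=degenerate,
        threshold=threshold,
    )
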