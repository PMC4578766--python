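"""Nested sampling for evidence estimation and posterior summaries.

The evidence ``Z = \\int L(p) pi(p) dp`` is rewritten as a one-dimensional
integral ``Z = \\int_0^1 L(X) dX`` over the prior mass ``X(lambda)`` enclosed
by the likelihood contour ``L > lambda``. An active set of ``n_live`` points
drawn from the prior is evolved by repeatedly removing the worst point (at
likelihood ``L*``) and replacing it with a fresh prior draw constrained to
``L > L*``; after ``k`` removals the enclosed prior mass has shrunk, in
expectation, to ``X_k = exp(-k / n_live)``. The integral is then the
staircase sum ``Z ~= sum_k h_k L_k`` with widths ``h_k = X_{k-1} - X_k``.

Each removed point doubles as a posterior sample with weight
``w_k = h_k L_k / Z``, giving weighted posterior means/sds for free and,
via resampling proportional to the weights ("staircase sampling"),
equally weighted posterior draws. The statistical uncertainty of ``ln Z``
is approximately ``sqrt(H / n_live)`` where ``H`` is the information (the
prior-to-posterior KL divergence).

Constrained replacement draws use a seeded random walk in the unit
hypercube (mapped through the prior's inverse CDF), started from a
surviving live point, with the step scale adapted between iterations to
keep the acceptance fraction in a healthy band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np

from .priors import PriorSpec

__all__ = [
    "NSConfig",
    "NSResult",
    "NestedSamplingError",
    "run",
    "constrained_draw",
    "posterior_summary",
    "staircase_sample",
]

logger = logging.getLogger(__name__)


class NestedSamplingError(RuntimeError):
    """Raised when the sampler cannot start or complete a run."""


@dataclass(frozen=True)
class NSConfig:
    """Sampler controls.

    Attributes
    ----------
    n_live : int
        Active-set size; the lnZ uncertainty scales as ``sqrt(H / n_live)``.
    max_mcmc_steps : int
        Length of each constrained random walk.
    termination_tolerance : float
        Stop when the largest possible remaining contribution
        ``L_max * X_k`` drops below this fraction of the accumulated Z.
    max_iterations : int
        Hard safety cap; hitting it flags the result instead of failing.
    seed : int
        Seed for the single generator driving all randomness.
    initial_step : float
        Starting value of the global step factor (steps are this factor
        times the live set's per-dimension spread).
    """

    n_live: int = 100
    max_mcmc_steps: int = 20
    termination_tolerance: float = 1e-6
    max_iterations: int = 200_000
    seed: int = 0
    initial_step: float = 1.0

    def __post_init__(self):
        if self.n_live < 2:
            raise ValueError("n_live must be at least 2")
        if not (0 < self.termination_tolerance < 1):
            raise ValueError("termination_tolerance must lie in (0, 1)")
        if self.max_mcmc_steps < 1 or self.max_iterations < 1:
            raise ValueError("step/iteration counts must be positive")


@dataclass
class NSResult:
    """Output of one nested-sampling run.

    ``samples``/``log_likelihoods``/``log_widths`` cover the removed points in
    removal order followed by the final live set; ``weights`` are the
    normalised posterior weights ``h_k L_k / Z``.
    """

    log_evidence: float
    log_evidence_sd: float
    samples: np.ndarray
    log_likelihoods: np.ndarray
    log_widths: np.ndarray
    weights: np.ndarray
    information_H: float
    n_iterations: int
    n_calls: int
    param_names: Tuple[str, ...]
    flagged: bool = False

    def summary(self, name_or_index) -> Tuple[float, float]:
        idx = (
            self.param_names.index(name_or_index)
            if isinstance(name_or_index, str)
            else int(name_or_index)
        )
        return posterior_summary(self, idx)


def _reflect(u: np.ndarray) -> np.ndarray:
    """Fold arbitrary coordinates back into [0, 1] by reflection."""
    return 1.0 - np.abs(1.0 - np.mod(u, 2.0))


def constrained_draw(
    live_u: np.ndarray,
    live_loglik: np.ndarray,
    l_star: float,
    loglik: Callable[[np.ndarray], float],
    spec: PriorSpec,
    config: NSConfig,
    rng: np.random.Generator,
    step_scale: float = 0.1,
) -> Tuple[np.ndarray, float, float]:
    """Draw a point from the prior restricted to ``loglik > l_star``.

    A random walk of ``config.max_mcmc_steps`` Gaussian steps in the unit
    cube (reflected at the boundaries), started from a uniformly chosen live
    point strictly above the constraint. Proposals are accepted whenever
    they satisfy the constraint, which leaves the constrained prior
    invariant. Returns ``(u, loglik(u), acceptance_fraction)``.

    ``step_scale`` is a global factor multiplying per-dimension step sizes
    set from the live set's spread in each unit-cube coordinate, so the
    proposal matches the anisotropy of the constrained region; the factor is
    adapted between iterations (frozen within a walk) to keep acceptance in
    a healthy band.

    If no live point lies strictly above ``l_star`` (a likelihood plateau),
    the walk starts from a random live point and accepts ``>=`` instead, so
    degenerate flat problems still mix. A walk with zero acceptances
    returns its start point with a warning.
    """
    above = np.nonzero(live_loglik > l_star)[0]
    strict = above.size > 0
    pool = above if strict else np.arange(live_u.shape[0])
    start = int(pool[rng.integers(pool.size)])
    u = live_u[start].copy()
    l_current = float(live_loglik[start])
    n_accept = 0
    dim = u.size
    spread = np.maximum(live_u.std(axis=0), 1e-10)
    steps = rng.standard_normal((config.max_mcmc_steps, dim)) * (step_scale * spread)
    transform = spec._transform_unchecked
    for k in range(config.max_mcmc_steps):
        proposal = _reflect(u + steps[k])
        l_new = loglik(transform(proposal))
        if (l_new > l_star) if strict else (l_new >= l_star):
            u = proposal
            l_current = l_new
            n_accept += 1
    if n_accept == 0:
        logger.warning("constrained walk accepted no proposals (L* = %.6g)", l_star)
    return u, l_current, n_accept / config.max_mcmc_steps


def run(
    loglik: Callable[[np.ndarray], float],
    spec: PriorSpec,
    config: Optional[NSConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> NSResult:
    """Estimate ``ln Z`` and posterior samples for a (likelihood, prior) pair.

    ``loglik`` maps a parameter vector (ordered as ``spec.names``) to a log
    likelihood; ``-inf`` marks zero-likelihood regions. Deterministic for a
    given ``config.seed`` (or caller-supplied generator).
    """
    config = config or NSConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_live
    dim = len(spec)

    live_u = rng.random((n, dim))
    live_x = np.array([spec.transform(u) for u in live_u])
    live_l = np.array([loglik(x) for x in live_x])
    n_calls = n
    if np.all(np.isneginf(live_l)):
        raise NestedSamplingError(
            "all initial live points have zero likelihood; check priors/support"
        )

    dead_u: list = []
    dead_l: list = []
    log_z = -np.inf
    log_zl = -np.inf  # sum h_k L_k lnL_k accumulator for H
    log_one_m = np.log1p(-np.exp(-1.0 / n))  # ln(1 - e^{-1/n})
    step_scale = config.initial_step
    flagged = False
    k = 0
    while True:
        k += 1
        worst = int(np.argmin(live_l))
        l_star = live_l[worst]
        log_h = -(k - 1) / n + log_one_m  # ln(X_{k-1} - X_k), X_j = e^{-j/n}
        if np.isfinite(l_star):
            log_z = np.logaddexp(log_z, log_h + l_star)
        dead_u.append(live_u[worst].copy())
        dead_l.append(float(l_star))
        u_new, l_new, acc = constrained_draw(
            live_u, live_l, l_star, loglik, spec, config, rng, step_scale
        )
        n_calls += config.max_mcmc_steps
        live_u[worst] = u_new
        live_l[worst] = l_new
        # adapt between iterations (frozen within each walk)
        if acc > 0.6:
            step_scale = min(step_scale * 1.5, 10.0)
        elif acc < 0.2:
            step_scale = max(step_scale * 0.5, 0.01)

        log_x = -k / n
        l_max = float(np.max(live_l))
        if np.isfinite(log_z) and l_max + log_x < np.log(config.termination_tolerance) + log_z:
            break
        if k >= config.max_iterations:
            flagged = True
            warnings.warn(
                "nested sampling hit max_iterations before reaching the "
                "termination tolerance; evidence may be underestimated",
                RuntimeWarning,
            )
            break

    # remaining live points: each carries width X_final / n_live
    log_x_final = -k / n
    order = np.argsort(live_l)
    log_h_live = log_x_final - np.log(n)
    log_widths = np.concatenate(
        [
            -(np.arange(1, k + 1) - 1) / n + log_one_m,
            np.full(n, log_h_live),
        ]
    )
    all_u = np.array(dead_u + [live_u[i] for i in order])
    all_l = np.concatenate([np.array(dead_l), live_l[order]])
    finite = np.isfinite(all_l)
    if finite.any():
        log_z = _logsumexp(log_widths[finite] + all_l[finite])
    samples = np.array([spec.transform(u) for u in all_u])

    with np.errstate(invalid="ignore"):
        log_w = log_widths + all_l - log_z
    weights = np.where(np.isfinite(log_w), np.exp(np.where(np.isfinite(log_w), log_w, -np.inf)), 0.0)
    total = weights.sum()
    if total > 0:
        weights = weights / total
    h = float(np.sum(weights[finite] * (all_l[finite] - log_z)))
    h = max(h, 0.0)
    return NSResult(
        log_evidence=float(log_z),
        log_evidence_sd=float(np.sqrt(h / n)),
        samples=samples,
        log_likelihoods=all_l,
        log_widths=log_widths,
        weights=weights,
        information_H=h,
        n_iterations=k,
        n_calls=n_calls,
        param_names=spec.names,
        flagged=flagged,
    )


def _logsumexp(a: np.ndarray) -> float:
    m = np.max(a)
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.sum(np.exp(a - m))))


def posterior_summary(result: NSResult, index: int) -> Tuple[float, float]:
    """Weighted posterior mean and sd of one parameter.

    ``mean = sum_k w_k p_k`` and ``sd = sqrt(sum_k w_k p_k^2 - mean^2)``,
    with tiny negative round-off clipped to zero.
    """
    if result.samples.shape[0] < 1:
        raise ValueError("empty result")
    p = result.samples[:, index]
    w = result.weights
    mean = float(np.sum(w * p))
    var = float(np.sum(w * p * p) - mean * mean)
    return mean, float(np.sqrt(max(var, 0.0)))


def staircase_sample(
    result: NSResult, count: int, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Equally weighted posterior draws by weight-proportional resampling."""
    if count <= 0:
        raise ValueError("count must be positive")
    rng = rng or np.random.default_rng()
    cum = np.cumsum(result.weights)
    cum /= cum[-1]
    idx = np.searchsorted(cum, rng.random(count), side="right")
    idx = np.clip(idx, 0, result.samples.shape[0] - 1)
    return result.samples[idx]
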