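"""Scikit-learn style estimators for growth-curve fitting.

:class:`BayesianGrowthRegressor` wraps the full nested-sampling analysis of
one curve (posterior over Baranyi–Roberts parameters plus the model
evidence); :class:`GrowthCurveRegressor` is the least-squares counterpart
used by the F-test baseline. Both follow the fit/predict contract with
``get_params``/``set_params`` and trailing-underscore fitted attributes, so
they compose with sklearn model-selection tooling. ``X`` is the time vector
in hours (shape ``(n, 1)`` or ``(n,)``), ``y`` the log10 concentration.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .growth_model import LN10, GrowthParams, predict_log10
from .likelihood import DEFAULT_TAIL_SD, GrowthCurve, NoiseSpec
from .nested_sampler import NSConfig, staircase_sample
from .priors import PriorEntry
from .comparison import fit_least_squares
from .synthetic_experiments import single_curve_evidence

__all__ = ["BayesianGrowthRegressor", "GrowthCurveRegressor"]


def _as_times(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("X must be a single time column")
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("X must be 1-d times or an (n, 1) column")
    return X


class BayesianGrowthRegressor(BaseEstimator, RegressorMixin):
    """Bayesian Baranyi–Roberts fit of a single growth curve.

    Parameters
    ----------
    noise_mode : {"inferred", "fixed"}
        Whether the log10 noise sd is inferred (Jeffreys prior) or fixed.
    sigma_fixed : float, optional
        The prescribed noise sd when ``noise_mode="fixed"``.
    mu_prior : PriorEntry, optional
        Informative prior for the growth rate (e.g. from
        :func:`bayesgrowth.priors.cluster_prior`); default is the
        data-scaled uniform.
    threshold : float, optional
        Detection limit (log10); observations below it are treated as
        censored.
    n_live, max_mcmc_steps, termination_tolerance, max_iterations, seed
        Nested-sampler controls (see :class:`bayesgrowth.nested_sampler.NSConfig`).

    Attributes
    ----------
    result_ : NSResult
        The raw nested-sampling output.
    log_evidence_, log_evidence_sd_ : float
        Model evidence ``ln Z`` and its uncertainty.
    params_mean_, params_sd_ : dict
        Posterior mean/sd per parameter (log10 scale).
    mu_max_, lag_time_ : float
        Posterior-mean growth rate (log10 units/h) and lag time (hours).
    sigma_ : float or None
        Posterior-mean noise sd when inferred.
    """

    def __init__(
        self,
        noise_mode: str = "inferred",
        sigma_fixed: Optional[float] = None,
        mu_prior: Optional[PriorEntry] = None,
        threshold: Optional[float] = None,
        tail_sd: float = DEFAULT_TAIL_SD,
        n_live: int = 100,
        max_mcmc_steps: int = 20,
        termination_tolerance: float = 1e-6,
        max_iterations: int = 200_000,
        seed: int = 0,
    ):
        self.noise_mode = noise_mode
        self.sigma_fixed = sigma_fixed
        self.mu_prior = mu_prior
        self.threshold = threshold
        self.tail_sd = tail_sd
        self.n_live = n_live
        self.max_mcmc_steps = max_mcmc_steps
        self.termination_tolerance = termination_tolerance
        self.max_iterations = max_iterations
        self.seed = seed

    def _config(self) -> NSConfig:
        return NSConfig(
            n_live=self.n_live,
            max_mcmc_steps=self.max_mcmc_steps,
            termination_tolerance=self.termination_tolerance,
            max_iterations=self.max_iterations,
            seed=self.seed,
        )

    def fit(self, X, y, censored=None):
        times = _as_times(X)
        y = np.asarray(y, dtype=float)
        curve = GrowthCurve(times, y, censored, self.threshold)
        noise = NoiseSpec(mode=self.noise_mode, sigma_fixed=self.sigma_fixed)
        result = single_curve_evidence(
            curve,
            mu_prior=self.mu_prior,
            config=self._config(),
            noise=noise,
            tail_sd=self.tail_sd,
        )
        self.n_features_in_ = 1
        self.curve_ = curve
        self.result_ = result
        self.log_evidence_ = result.log_evidence
        self.log_evidence_sd_ = result.log_evidence_sd
        self.params_mean_ = {}
        self.params_sd_ = {}
        for name in result.param_names:
            mean, sd = result.summary(name)
            self.params_mean_[name] = mean
            self.params_sd_[name] = sd
        self.mu_max_ = self.params_mean_["mu_max"]
        self.sigma_ = self.params_mean_.get("sigma")
        # lag = h0 / mu_ln, averaged over the weighted posterior
        i_h0 = result.param_names.index("h0")
        i_mu = result.param_names.index("mu_max")
        lag = result.samples[:, i_h0] / (result.samples[:, i_mu] * LN10)
        self.lag_time_ = float(np.sum(result.weights * lag))
        return self

    def _posterior_mean_params(self) -> GrowthParams:
        check_is_fitted(self, "result_")
        m = self.params_mean_
        return GrowthParams(y0=m["y0"], mu_max=m["mu_max"], h0=m["h0"], ymax=m["ymax"])

    def predict(self, X) -> np.ndarray:
        """Posterior-mean-parameter growth curve (log10 concentration)."""
        check_is_fitted(self, "result_")
        return np.asarray(predict_log10(_as_times(X), self._posterior_mean_params()))

    def sample_posterior(self, n: int = 1000, seed: Optional[int] = None) -> np.ndarray:
        """Equally weighted posterior parameter draws (staircase sampling)."""
        check_is_fitted(self, "result_")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        return staircase_sample(self.result_, n, rng)


class GrowthCurveRegressor(BaseEstimator, RegressorMixin):
    """Multistart least-squares Baranyi–Roberts fit of a single curve."""

    def __init__(self, n_starts: int = 10, seed: int = 0):
        self.n_starts = n_starts
        self.seed = seed

    def fit(self, X, y):
        times = _as_times(X)
        y = np.asarray(y, dtype=float)
        curve = GrowthCurve(times, y)
        ls = fit_least_squares([curve], "separated", n_starts=self.n_starts, seed=self.seed)
        self.n_features_in_ = 1
        self.growth_params_ = ls.params[0]
        self.mu_max_ = ls.params[0].mu_max
        self.lag_time_ = ls.params[0].h0 / (ls.params[0].mu_max * LN10)
        self.ssr_ = ls.ssr
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "growth_params_")
        return np.asarray(predict_log10(_as_times(X), self.growth_params_))
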