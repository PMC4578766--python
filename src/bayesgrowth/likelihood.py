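"""Log-likelihood of a growth curve under the Baranyi–Roberts model.

Viable-count errors are log-normally distributed in concentration, hence
Gaussian on the log10 scale, with a single constant noise level ``sigma``
(either prescribed or inferred under a Jeffreys prior; see
:mod:`bayesgrowth.priors`). For ``N`` observations ``d_i`` at times ``t_i``
with model values ``y_i``::

    log L = -sum_i ln(sigma * sqrt(2*pi)) - (1/2) * sum_i (d_i - y_i)^2 / sigma^2

Observations below the detection limit of the plating method (recorded with a
``censored`` flag) instead contribute a uniform density on ``[0, threshold]``
of the log10 scale — ``ln(1/threshold)`` — expressing total ignorance of the
position below the limit; a small Gaussian tail above the threshold replaces
the hard zero to keep the log-likelihood finite for samplers. Common detection
thresholds are 0.7 and 1.3 log10 CFU.

All functions here take data *and* model parameters on the log10 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from .growth_model import GrowthParams, predict_log10

__all__ = [
    "GrowthCurve",
    "NoiseSpec",
    "DEFAULT_TAIL_SD",
    "DETECTION_THRESHOLDS",
    "gaussian_loglik",
    "censored_point_loglik",
    "curve_loglik",
    "joint_loglik",
    "make_curve_loglik",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

#: Soft width (log10 units) of the Gaussian tail above the detection
#: threshold; small relative to typical data noise so the tail acts as a
#: barrier rather than a likelihood contribution.
DEFAULT_TAIL_SD = 0.05

#: Conventional detection limits (log10 CFU) of plating methods.
DETECTION_THRESHOLDS = (0.7, 1.3)


@dataclass(frozen=True)
class GrowthCurve:
    """One observed growth curve: times (h) vs log10 concentration.

    ``censored[i]`` marks observation ``i`` as below the detection limit;
    ``threshold`` (log10 scale) is required whenever any flag is set, and
    censored recorded values may not exceed it.
    """

    times: np.ndarray
    values: np.ndarray
    censored: np.ndarray = None  # type: ignore[assignment]
    threshold: Optional[float] = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        censored = (
            np.zeros(times.shape, dtype=bool)
            if self.censored is None
            else np.asarray(self.censored, dtype=bool)
        )
        if times.ndim != 1 or times.size < 2:
            raise ValueError("a curve needs at least two time points")
        if values.shape != times.shape or censored.shape != times.shape:
            raise ValueError("times, values and censored must have equal length")
        if np.any(~np.isfinite(times)) or np.any(~np.isfinite(values)):
            raise ValueError("times and values must be finite")
        if np.any(times < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if censored.any():
            if self.threshold is None:
                raise ValueError("a detection threshold is required for censored points")
            if not self.threshold > 0:
                raise ValueError("threshold must be positive")
            if np.any(values[censored] > self.threshold):
                raise ValueError("censored values must lie at or below the threshold")
        elif self.threshold is not None and not self.threshold > 0:
            raise ValueError("threshold must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "censored", censored)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    @property
    def value_range(self) -> float:
        return float(self.values.max() - self.values.min())


@dataclass(frozen=True)
class NoiseSpec:
    """Noise-level treatment: prescribed (``fixed``) or inferred.

    When inferred, ``sigma`` gets a Jeffreys prior (density proportional to
    1/sigma) supported on ``bounds``.
    """

    mode: str = "inferred"
    sigma_fixed: Optional[float] = None
    bounds: Tuple[float, float] = (1e-3, 10.0)

    def __post_init__(self):
        if self.mode not in ("fixed", "inferred"):
            raise ValueError("mode must be 'fixed' or 'inferred'")
        if self.mode == "fixed":
            if self.sigma_fixed is None or not self.sigma_fixed > 0:
                raise ValueError("fixed mode requires a positive sigma_fixed")
        lo, hi = self.bounds
        if not (0 < lo < hi):
            raise ValueError("noise bounds must satisfy 0 < low < high")


def _gaussian_terms(residuals: np.ndarray, sigma: float) -> float:
    n = residuals.size
    return float(
        -n * (np.log(sigma) + _LOG_SQRT_2PI)
        - 0.5 * np.dot(residuals, residuals) / (sigma * sigma)
    )


def gaussian_loglik(curve: GrowthCurve, params: GrowthParams, sigma: float) -> float:
    """Gaussian log-likelihood of an uncensored curve (log10 scale)."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if curve.censored.any():
        raise ValueError("gaussian_loglik expects no censored points")
    residuals = curve.values - predict_log10(curve.times, params)
    return _gaussian_terms(residuals, sigma)


def censored_point_loglik(predicted: float, threshold: float, tail_sd: float = DEFAULT_TAIL_SD) -> float:
    """Log density of one below-detection observation given the model value.

    Flat at ``ln(1/threshold)`` while the model stays below the threshold; a
    Gaussian tail (width ``tail_sd``) penalises model values above it. The
    tail is an unnormalised barrier, continuous at the threshold.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if not tail_sd > 0:
        raise ValueError("tail_sd must be positive")
    base = -np.log(threshold)
    excess = predicted - threshold
    if excess <= 0:
        return float(base)
    return float(base - 0.5 * excess * excess / (tail_sd * tail_sd))


def curve_loglik(
    curve: GrowthCurve,
    params: GrowthParams,
    sigma: float,
    tail_sd: float = DEFAULT_TAIL_SD,
) -> float:
    """Full-curve log-likelihood: Gaussian points plus censored points."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if not tail_sd > 0:
        raise ValueError("tail_sd must be positive")
    predicted = np.asarray(predict_log10(curve.times, params))
    cens = curve.censored
    total = 0.0
    if (~cens).any():
        residuals = curve.values[~cens] - predicted[~cens]
        total += _gaussian_terms(residuals, sigma)
    if cens.any():
        thr = curve.threshold
        excess = np.maximum(predicted[cens] - thr, 0.0)
        total += float(
            -cens.sum() * np.log(thr)
            - 0.5 * np.dot(excess, excess) / (tail_sd * tail_sd)
        )
    return total


def joint_loglik(
    curve_a: GrowthCurve,
    curve_b: GrowthCurve,
    params_a: GrowthParams,
    params_b: GrowthParams,
    sigma: Union[float, Tuple[float, float]],
    tail_sd: float = DEFAULT_TAIL_SD,
) -> float:
    """Combined log-likelihood of two independent curves.

    ``sigma`` may be a single shared noise level (the default treatment) or a
    ``(sigma_a, sigma_b)`` pair for per-curve noise.
    """
    if isinstance(sigma, tuple):
        sig_a, sig_b = sigma
    else:
        sig_a = sig_b = sigma
    return curve_loglik(curve_a, params_a, sig_a, tail_sd) + curve_loglik(
        curve_b, params_b, sig_b, tail_sd
    )


def make_curve_loglik(curve: GrowthCurve, tail_sd: float = DEFAULT_TAIL_SD):
    """Build a fast validation-free log-likelihood kernel for one curve.

    Returns ``f(y0, mu_max, h0, ymax, sigma) -> float`` with all parameters on
    the log10 scale; off-support inputs (``ymax <= y0``, non-positive rate or
    noise) return ``-inf`` rather than raising. Used by the sampler hot loop,
    where per-call validation would dominate the cost; compiled with numba
    when available.
    """
    from functools import partial

    from ._kernels import curve_loglik_kernel

    times = np.ascontiguousarray(curve.times, dtype=float)
    values = np.ascontiguousarray(curve.values, dtype=float)
    cens = np.ascontiguousarray(curve.censored, dtype=bool)
    thr = float(curve.threshold) if curve.threshold is not None else 1.0
    inv_tail2 = 0.5 / (tail_sd * tail_sd)
    return partial(curve_loglik_kernel, times, values, cens, thr, inv_tail2)
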