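"""Baranyi–Roberts growth model.

The model describes the logarithm of a bacterial concentration through lag,
exponential and stationary phase::

    y(t) = y0 + mu_max * A(t) - ln(1 + (exp(mu_max * A(t)) - 1) / exp(ymax - y0))

with the adjustment function

    A(t) = t - h0/mu_max + ln(1 - exp(-mu_max*t) + exp(-(mu_max*t - h0))) / mu_max

where ``y = ln x`` for concentration ``x``, ``y0 = ln x(0)``, ``ymax`` is the
natural log of the carrying capacity, ``mu_max`` the maximum specific growth
rate (per hour) and ``h0 = lag_time * mu_max`` a dimensionless lag parameter.

Both equations are written — and evaluated here — on the natural-log scale.
Microbiological data and reported results conventionally use log10
concentrations; :func:`convert_scale` and :func:`predict_log10` handle the
conversion (``y``, ``y0``, ``ymax`` and ``mu_max`` all scale by ``ln 10``;
``h0`` is scale invariant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np

__all__ = [
    "GrowthParams",
    "MODEL_VARIANTS",
    "NATURAL_LOG",
    "LOG10",
    "adjustment",
    "predict",
    "predict_log10",
    "convert_scale",
    "lag_time",
]

NATURAL_LOG = "natural_log"
LOG10 = "log10"
_SCALES = (NATURAL_LOG, LOG10)
LN10 = math.log(10.0)

#: Reduced model variants, defined as parameter restrictions of the full
#: four-parameter model: name -> (free parameter names, fixed values).
MODEL_VARIANTS = {
    "full": (("y0", "mu_max", "h0", "ymax"), {}),
    "no_lag": (("y0", "mu_max", "ymax"), {"h0": 0.0}),
    "no_stationary": (("y0", "mu_max", "h0"), {"ymax": np.inf}),
    "linear": (("y0", "mu_max"), {"h0": 0.0, "ymax": np.inf}),
}


@dataclass(frozen=True)
class GrowthParams:
    """Baranyi–Roberts parameter vector.

    Parameters are interpreted on whichever concentration scale the caller is
    working on (natural log inside the model equations, log10 for data and
    reporting); ``h0`` is dimensionless and identical on both scales.

    Attributes
    ----------
    y0 : float
        Log concentration at t=0.
    mu_max : float
        Maximum specific growth rate (per hour), strictly positive.
    h0 : float
        Dimensionless lag parameter, ``h0 = lag_time * mu_max``, non-negative.
    ymax : float
        Log maximum concentration; must exceed ``y0``. ``inf`` denotes the
        no-stationary-phase restriction.
    sigma : float, optional
        Noise standard deviation in log-concentration units.
    """

    y0: float
    mu_max: float
    h0: float
    ymax: float
    sigma: Optional[float] = None

    def __post_init__(self):
        if not np.isfinite(self.y0):
            raise ValueError("y0 must be finite")
        if not (self.mu_max > 0) or not np.isfinite(self.mu_max):
            raise ValueError("mu_max must be positive and finite")
        if self.h0 < 0 or not np.isfinite(self.h0):
            raise ValueError("h0 must be non-negative and finite")
        if not self.ymax > self.y0:
            raise ValueError("ymax must exceed y0")
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError("sigma must be positive when given")

    @property
    def lag_time(self) -> float:
        """Lag-phase duration ``lambda = h0 / mu_max`` (hours on this scale)."""
        return self.h0 / self.mu_max

    def as_array(self) -> np.ndarray:
        return np.array([self.y0, self.mu_max, self.h0, self.ymax], dtype=float)


def _validate_t(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ValueError("times must be finite and non-negative")
    return t


def adjustment(t, mu_max: float, h0: float):
    """Adjustment function A(t) encoding the lag phase.

    Equals ``t`` for ``h0 = 0`` and approaches the shifted asymptote
    ``t - h0/mu_max`` once ``mu_max*t >> h0``. Evaluated with a shifted
    log-sum-exp so that ``mu_max*t`` (and ``h0``) up to ~700 stay finite.
    """
    if not mu_max > 0:
        raise ValueError("mu_max must be positive")
    if h0 < 0:
        raise ValueError("h0 must be non-negative")
    t_arr = _validate_t(t)
    if h0 == 0:
        return t_arr if t_arr.ndim else float(t_arr)

    mt = mu_max * t_arr
    b = h0 - mt
    m = np.maximum(0.0, b)
    # ln(1 - exp(-mt) + exp(b)); argument is always > 0 for mt >= 0
    inner = m + np.log(np.exp(-m) - np.exp(-mt - m) + np.exp(b - m))
    out = t_arr - h0 / mu_max + inner / mu_max
    out = np.where(t_arr == 0.0, 0.0, out)
    return out if out.ndim else float(out)


def predict(t, params: GrowthParams):
    """Log concentration y(t) on the natural-log scale.

    Non-decreasing in ``t`` with ``y(0) = y0`` and ``y -> ymax`` as
    ``t -> inf``. Uses the algebraically equivalent form
    ``y = y0 + g + m - ln(e^g + e^m - 1)`` with ``g = ymax - y0`` and
    ``m = mu_max * A(t)``, stabilised by a log-sum-exp shift.
    """
    t_arr = _validate_t(t)
    m = params.mu_max * np.asarray(adjustment(t_arr, params.mu_max, params.h0))
    g = params.ymax - params.y0
    if np.isinf(g):
        out = params.y0 + m
    else:
        big = np.maximum(g, m)
        arg = np.exp(g - big) + np.exp(m - big) - np.exp(-big)
        out = params.y0 + g + m - big - np.log(np.maximum(arg, np.finfo(float).tiny))
        out = np.where(m == 0.0, params.y0, out)
    return out if out.ndim else float(out)


def predict_log10(t, params: GrowthParams):
    """Model prediction in log10 units for parameters given in log10 units."""
    return predict(t, convert_scale(params, LOG10, NATURAL_LOG)) / LN10


def lag_time(params: GrowthParams, scale: str = LOG10) -> float:
    """Lag duration in hours for parameters expressed on ``scale``."""
    _check_scale(scale)
    mu_ln = params.mu_max * LN10 if scale == LOG10 else params.mu_max
    return params.h0 / mu_ln


def _check_scale(scale: str) -> None:
    if scale not in _SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {_SCALES}")


def convert_scale(
    value: Union[float, np.ndarray, GrowthParams],
    from_scale: str,
    to_scale: str,
):
    """Convert a log concentration (or a full parameter set) between scales.

    Natural-log quantities divide by ``ln 10`` to reach log10 and vice versa;
    ``h0`` is untouched. Round-trips are exact to floating-point rounding.
    """
    _check_scale(from_scale)
    _check_scale(to_scale)
    if from_scale == to_scale:
        return value
    factor = 1.0 / LN10 if to_scale == LOG10 else LN10
    if isinstance(value, GrowthParams):
        return replace(
            value,
            y0=value.y0 * factor,
            mu_max=value.mu_max * factor,
            ymax=value.ymax * factor,
            sigma=None if value.sigma is None else value.sigma * factor,
        )
    return value * factor
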