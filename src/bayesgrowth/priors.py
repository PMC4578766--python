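"""Prior distributions for growth-model parameters.

Four families are supported per parameter: uniform (the uninformative
default, with bounds scaled to the data), truncated Gaussian and truncated
Cauchy (informative priors for the growth rate, typically built from a
cluster of previously analysed curves), and a bounded Jeffreys prior
(density proportional to 1/sigma) for the noise level.

A cluster of ``N`` previously analysed curves with inferred growth-rate
means ``mu_i`` and variances ``sigma_i^2`` collapses to a single location
and spread via the law of total variance::

    mu_cluster      = mean(mu_i)
    sigma_cluster^2 = mean(mu_i^2) - mean(mu_i)^2 + mean(sigma_i^2)

which then serve as the location/scale of a Gaussian or Cauchy prior. The
heavy-tailed Cauchy expresses weaker confidence in the cluster: it keeps
appreciable mass far outside the high-probability region.

Sampling uses the inverse-CDF map from the unit hypercube
(:meth:`PriorSpec.transform`), so the nested sampler only ever works with
uniform coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy.special import ndtr, ndtri

from .likelihood import GrowthCurve, NoiseSpec

__all__ = [
    "PriorEntry",
    "PriorSpec",
    "ClusterSummary",
    "MU_EPSILON",
    "default_bounds",
    "cluster_prior",
    "prior_transform",
    "log_prior_density",
]

#: Lower bound for the growth-rate prior; keeps the adjustment function
#: well-defined (mu_max must be strictly positive).
MU_EPSILON = 1e-6

_KINDS = ("uniform", "gaussian", "cauchy", "jeffreys")
_KIND_CODE = {k: i for i, k in enumerate(_KINDS)}


def _cauchy_cdf(x, loc, scale):
    return 0.5 + np.arctan((x - loc) / scale) / np.pi


def _cauchy_ppf(q, loc, scale):
    return loc + scale * np.tan(np.pi * (q - 0.5))


@dataclass(frozen=True)
class PriorEntry:
    """One parameter's prior: a family plus its truncation interval.

    ``loc``/``scale`` are the Gaussian mean/sd or the Cauchy location/scale
    and are ignored for uniform and Jeffreys entries. Densities are
    normalised over ``[lower, upper]``.
    """

    kind: str
    lower: float
    upper: float
    loc: Optional[float] = None
    scale: Optional[float] = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if not self.lower < self.upper:
            raise ValueError("prior requires lower < upper")
        if self.kind in ("gaussian", "cauchy"):
            if self.loc is None or self.scale is None or not self.scale > 0:
                raise ValueError(f"{self.kind} prior needs loc and positive scale")
        if self.kind == "jeffreys" and not self.lower > 0:
            raise ValueError("jeffreys prior needs strictly positive bounds")

    # -- single-entry maps (vectorised over x / u) ---------------------------
    def transform(self, u):
        """Inverse-CDF map from [0, 1] onto [lower, upper]."""
        u = np.asarray(u, dtype=float)
        if np.any(u < 0) or np.any(u > 1):
            raise ValueError("u must lie in the unit interval")
        if self.kind == "uniform":
            out = self.lower + u * (self.upper - self.lower)
        elif self.kind == "jeffreys":
            out = self.lower * (self.upper / self.lower) ** u
        elif self.kind == "gaussian":
            a = ndtr((self.lower - self.loc) / self.scale)
            b = ndtr((self.upper - self.loc) / self.scale)
            out = self.loc + self.scale * ndtri(a + u * (b - a))
        else:  # cauchy
            a = _cauchy_cdf(self.lower, self.loc, self.scale)
            b = _cauchy_cdf(self.upper, self.loc, self.scale)
            out = _cauchy_ppf(a + u * (b - a), self.loc, self.scale)
        out = np.clip(out, self.lower, self.upper)
        return out if out.ndim else float(out)

    def cdf(self, x):
        """CDF of the truncated distribution (inverse of :meth:`transform`)."""
        x = np.asarray(x, dtype=float)
        if self.kind == "uniform":
            out = (x - self.lower) / (self.upper - self.lower)
        elif self.kind == "jeffreys":
            out = np.log(x / self.lower) / np.log(self.upper / self.lower)
        elif self.kind == "gaussian":
            a = ndtr((self.lower - self.loc) / self.scale)
            b = ndtr((self.upper - self.loc) / self.scale)
            out = (ndtr((x - self.loc) / self.scale) - a) / (b - a)
        else:
            a = _cauchy_cdf(self.lower, self.loc, self.scale)
            b = _cauchy_cdf(self.upper, self.loc, self.scale)
            out = (_cauchy_cdf(x, self.loc, self.scale) - a) / (b - a)
        return out if out.ndim else float(out)

    def log_density(self, x):
        """Log density, normalised over the truncation interval.

        Returns ``-inf`` outside ``[lower, upper]``.
        """
        x = np.asarray(x, dtype=float)
        inside = (x >= self.lower) & (x <= self.upper)
        if self.kind == "uniform":
            out = np.full(x.shape, -math.log(self.upper - self.lower))
        elif self.kind == "jeffreys":
            with np.errstate(invalid="ignore", divide="ignore"):
                out = -np.log(x) - math.log(math.log(self.upper / self.lower))
        elif self.kind == "gaussian":
            a = ndtr((self.lower - self.loc) / self.scale)
            b = ndtr((self.upper - self.loc) / self.scale)
            z = (x - self.loc) / self.scale
            out = -0.5 * z * z - 0.5 * math.log(2 * math.pi) - math.log(self.scale) - math.log(b - a)
        else:
            a = _cauchy_cdf(self.lower, self.loc, self.scale)
            b = _cauchy_cdf(self.upper, self.loc, self.scale)
            z = (x - self.loc) / self.scale
            out = -np.log1p(z * z) - math.log(math.pi * self.scale) - math.log(b - a)
        out = np.where(inside, out, -np.inf)
        return out if out.ndim else float(out)

    def to_dict(self) -> Dict[str, float]:
        d: Dict[str, float] = {"kind": self.kind, "lower": self.lower, "upper": self.upper}
        if self.loc is not None:
            d["loc"] = self.loc
        if self.scale is not None:
            d["scale"] = self.scale
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PriorEntry":
        allowed = {"kind", "lower", "upper", "loc", "scale"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown prior fields: {sorted(unknown)}")
        return cls(**d)


class PriorSpec:
    """Ordered collection of per-parameter priors with a joint support rule.

    The joint constraint ``ymax > y0`` (when both parameters are present and
    ``joint_ymax_gt_y0`` is set) is imposed as zero prior mass rather than by
    reparameterising; samplers reject such points through the likelihood.
    """

    def __init__(self, entries: Mapping[str, PriorEntry], joint_ymax_gt_y0: bool = True):
        if not entries:
            raise ValueError("PriorSpec needs at least one entry")
        self._entries: Dict[str, PriorEntry] = dict(entries)
        self.joint_ymax_gt_y0 = bool(joint_ymax_gt_y0) and (
            "y0" in self._entries and "ymax" in self._entries
        )
        self.names: Tuple[str, ...] = tuple(self._entries)
        self._build_tables()

    def _build_tables(self):
        n = len(self.names)
        self._codes = np.array([_KIND_CODE[self._entries[k].kind] for k in self.names])
        self._lower = np.array([self._entries[k].lower for k in self.names])
        self._upper = np.array([self._entries[k].upper for k in self.names])
        loc = np.array([self._entries[k].loc or 0.0 for k in self.names])
        scale = np.array(
            [self._entries[k].scale if self._entries[k].scale else 1.0 for k in self.names]
        )
        self._loc, self._scale = loc, scale
        # pre-computed truncation CDF values for gaussian/cauchy entries
        self._ga = ndtr((self._lower - loc) / scale)
        self._gb = ndtr((self._upper - loc) / scale)
        self._ca = _cauchy_cdf(self._lower, loc, scale)
        self._cb = _cauchy_cdf(self._upper, loc, scale)
        self._log_ratio = np.array(
            [
                math.log(e.upper / e.lower) if e.kind == "jeffreys" else 0.0
                for e in (self._entries[k] for k in self.names)
            ]
        )
        self._iy0 = self.names.index("y0") if "y0" in self.names else -1
        self._iymax = self.names.index("ymax") if "ymax" in self.names else -1
        self._all_uniform = bool(np.all(self._codes == 0))
        self._width = self._upper - self._lower
        self._idx_gauss = np.nonzero(self._codes == 1)[0]
        self._idx_cauchy = np.nonzero(self._codes == 2)[0]
        self._idx_jeff = np.nonzero(self._codes == 3)[0]
        # scalar per-entry records for the sampler hot path
        self._nonuniform = [
            (int(i), int(self._codes[i])) for i in np.nonzero(self._codes != 0)[0]
        ]

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> PriorEntry:
        return self._entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def items(self):
        return self._entries.items()

    def replace(self, **overrides: PriorEntry) -> "PriorSpec":
        """New spec with some entries swapped (e.g. an informative mu_max)."""
        unknown = set(overrides) - set(self.names)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        entries = dict(self._entries)
        entries.update(overrides)
        return PriorSpec(entries, joint_ymax_gt_y0=self.joint_ymax_gt_y0)

    def transform(self, u: np.ndarray) -> np.ndarray:
        """Map a unit-hypercube point to a parameter vector (inverse CDF).

        Monotone in every component; vectorisation over the parameter axis
        keeps this cheap inside the sampler's walk.
        """
        u = np.asarray(u, dtype=float)
        if u.shape != (len(self.names),):
            raise ValueError(f"expected u of shape ({len(self.names)},)")
        if np.any(u < 0) or np.any(u > 1):
            raise ValueError("u must lie in the unit hypercube")
        return self._transform_unchecked(u)

    def _transform_unchecked(self, u: np.ndarray) -> np.ndarray:
        """Inverse-CDF map without input validation (sampler hot path)."""
        out = self._lower + u * self._width  # uniform default
        if self._all_uniform:
            return out
        for i, code in self._nonuniform:
            ui = u[i]
            if code == 3:  # jeffreys
                x = self._lower[i] * math.exp(ui * self._log_ratio[i])
            elif code == 1:  # truncated gaussian
                q = self._ga[i] + ui * (self._gb[i] - self._ga[i])
                x = self._loc[i] + self._scale[i] * float(ndtri(q))
            else:  # truncated cauchy
                q = self._ca[i] + ui * (self._cb[i] - self._ca[i])
                x = self._loc[i] + self._scale[i] * math.tan(math.pi * (q - 0.5))
            out[i] = min(max(x, self._lower[i]), self._upper[i])
        return out

    def log_density(self, params: np.ndarray) -> float:
        """Joint log prior density; ``-inf`` off support (not an error)."""
        params = np.asarray(params, dtype=float)
        if params.shape != (len(self.names),):
            raise ValueError(f"expected parameter vector of shape ({len(self.names)},)")
        if self.joint_ymax_gt_y0 and params[self._iymax] <= params[self._iy0]:
            return -np.inf
        total = 0.0
        for name, value in zip(self.names, params):
            total += self._entries[name].log_density(value)
            if total == -np.inf:
                return -np.inf
        return float(total)

    def as_dict(self) -> Dict[str, Dict[str, float]]:
        return {name: entry.to_dict() for name, entry in self._entries.items()}

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping], joint_ymax_gt_y0: bool = True) -> "PriorSpec":
        return cls({k: PriorEntry.from_dict(v) for k, v in d.items()}, joint_ymax_gt_y0)


@dataclass(frozen=True)
class ClusterSummary:
    """Growth-rate posteriors of previously analysed curves in one cluster."""

    member_means: np.ndarray
    member_variances: np.ndarray

    def __post_init__(self):
        means = np.atleast_1d(np.asarray(self.member_means, dtype=float))
        variances = np.atleast_1d(np.asarray(self.member_variances, dtype=float))
        if means.size == 0:
            raise ValueError("a cluster needs at least one member")
        if variances.shape != means.shape:
            raise ValueError("means and variances must align")
        if np.any(variances < 0):
            raise ValueError("variances must be non-negative")
        object.__setattr__(self, "member_means", means)
        object.__setattr__(self, "member_variances", variances)

    @property
    def mean(self) -> float:
        """Cluster growth-rate location: the average of member means."""
        return float(self.member_means.mean())

    @property
    def variance(self) -> float:
        """Law-of-total-variance spread: between-member plus mean within-member."""
        m = self.member_means
        return float(np.mean(m * m) - m.mean() ** 2 + self.member_variances.mean())


def default_bounds(
    curve: GrowthCurve,
    noise: Optional[NoiseSpec] = None,
    variant: str = "full",
) -> PriorSpec:
    """Uninformative data-scaled priors for one curve.

    With data range ``r = d_max - d_min`` (floored at 1 for near-constant
    curves) and time span ``t_max - t_min``:

    - ``y0``     uniform on ``[d_min - r/2, d_max]``
    - ``ymax``   uniform on ``[d_min, d_max + r/2]`` (joint support ymax > y0)
    - ``mu_max`` uniform on ``(MU_EPSILON, 10 r / (t_max - t_min)]``
    - ``h0``     uniform on ``[0, mu_upper * t_max]``
    - ``sigma``  Jeffreys on ``[1e-3, r]`` when the noise level is inferred

    Reduced model variants drop the corresponding entries.
    """
    from .growth_model import MODEL_VARIANTS

    if variant not in MODEL_VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    if len(curve) < 2:
        raise ValueError("need at least two points")
    t_span = float(curve.times.max() - curve.times.min())
    if t_span <= 0:
        raise ValueError("zero time span")
    d_min = float(curve.values.min())
    d_max = float(curve.values.max())
    r = max(d_max - d_min, 1.0)
    mu_upper = 10.0 * r / t_span
    free, _ = MODEL_VARIANTS[variant]
    entries: Dict[str, PriorEntry] = {}
    if "y0" in free:
        entries["y0"] = PriorEntry("uniform", d_min - r / 2.0, d_max)
    if "mu_max" in free:
        entries["mu_max"] = PriorEntry("uniform", MU_EPSILON, mu_upper)
    if "h0" in free:
        entries["h0"] = PriorEntry("uniform", 0.0, mu_upper * float(curve.times.max()))
    if "ymax" in free:
        entries["ymax"] = PriorEntry("uniform", d_min, d_max + r / 2.0)
    noise = noise or NoiseSpec()
    if noise.mode == "inferred":
        # data-scaled rule intersected with any user-supplied support
        lo = max(1e-3, noise.bounds[0])
        hi = min(r, noise.bounds[1])
        if not lo < hi:
            raise ValueError("noise bounds do not overlap the data-scaled sigma range")
        entries["sigma"] = PriorEntry("jeffreys", lo, hi)
    return PriorSpec(entries)


def cluster_prior(
    summary: ClusterSummary,
    kind: str = "gaussian",
    bounds: Optional[Tuple[float, float]] = None,
) -> PriorEntry:
    """Informative growth-rate prior from a cluster of analysed curves.

    The cluster mean and total-variance spread become the location and scale
    of a truncated Gaussian or Cauchy. ``bounds`` default to location
    +/- 10 scale intersected with positivity (``MU_EPSILON``).
    """
    if kind not in ("gaussian", "cauchy"):
        raise ValueError("cluster prior kind must be 'gaussian' or 'cauchy'")
    loc = summary.mean
    scale = math.sqrt(summary.variance)
    if scale == 0:
        raise ValueError("cluster has zero total variance; cannot set a prior scale")
    if bounds is None:
        bounds = (max(MU_EPSILON, loc - 10 * scale), loc + 10 * scale)
    lower, upper = bounds
    return PriorEntry(kind, lower, upper, loc=loc, scale=scale)


def prior_transform(u: np.ndarray, spec: PriorSpec) -> np.ndarray:
    """Functional alias for :meth:`PriorSpec.transform`."""
    return spec.transform(u)


def log_prior_density(params: np.ndarray, spec: PriorSpec) -> float:
    """Functional alias for :meth:`PriorSpec.log_density`."""
    return spec.log_density(params)
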