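"""File formats and run configuration.

Curve files are plain delimited text with header ``time,logc[,censored]``:
time in hours (strictly increasing), ``logc`` the log10 concentration and
an optional 0/1 censoring flag for below-detection observations. Cluster
files are ``mean,variance`` rows summarising previously inferred growth
rates. Run configuration is YAML with a fixed schema; unknown keys are
rejected so typos cannot silently change an analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .likelihood import GrowthCurve, NoiseSpec
from .nested_sampler import NSConfig
from .priors import ClusterSummary, PriorEntry

__all__ = [
    "CurveParseError",
    "RunConfig",
    "read_curve",
    "write_curve",
    "read_cluster_file",
    "load_config",
    "config_digest",
]


class CurveParseError(ValueError):
    """A curve file violated the format contract."""


def read_curve(path, threshold: Optional[float] = None) -> GrowthCurve:
    """Parse a ``time,logc[,censored]`` file into a :class:`GrowthCurve`.

    Malformed rows are reported with their line numbers; a configured
    ``threshold`` is required when any row is flagged censored.
    """
    path = Path(path)
    if not path.exists():
        raise CurveParseError(f"{path}: no such file")
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise CurveParseError(f"{path}: cannot parse ({exc})") from exc
    cols = [c.strip().lower() for c in frame.columns]
    if cols[:2] != ["time", "logc"] or len(cols) > 3 or (len(cols) == 3 and cols[2] != "censored"):
        raise CurveParseError(
            f"{path}: header must be 'time,logc' or 'time,logc,censored', got {list(frame.columns)}"
        )
    frame.columns = cols
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric[["time", "logc"]].isna().any(axis=1) | frame[["time", "logc"]].isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in numeric.index[bad]]  # +2: header + 1-based
        raise CurveParseError(f"{path}: non-numeric or missing values on line(s) {lines}")
    times = numeric["time"].to_numpy(float)
    values = numeric["logc"].to_numpy(float)
    censored = None
    if "censored" in cols:
        flags = numeric["censored"].fillna(0.0)
        if not flags.isin([0.0, 1.0]).all():
            lines = [int(i) + 2 for i in flags.index[~flags.isin([0.0, 1.0])]]
            raise CurveParseError(f"{path}: censored flag must be 0 or 1 on line(s) {lines}")
        censored = flags.to_numpy(bool)
    if np.any(np.diff(times) <= 0):
        i = int(np.nonzero(np.diff(times) <= 0)[0][0])
        raise CurveParseError(f"{path}: times must be strictly increasing (line {i + 3})")
    try:
        return GrowthCurve(times, values, censored, threshold)
    except ValueError as exc:
        raise CurveParseError(f"{path}: {exc}") from exc


def write_curve(curve: GrowthCurve, path) -> None:
    """Write a curve back to ``time,logc[,censored]`` text."""
    data = {"time": curve.times, "logc": curve.values}
    if curve.censored.any():
        data["censored"] = curve.censored.astype(int)
    pd.DataFrame(data).to_csv(path, index=False)


def read_cluster_file(path) -> ClusterSummary:
    """Parse ``mean,variance`` rows (header optional) into a cluster summary."""
    path = Path(path)
    if not path.exists():
        raise CurveParseError(f"{path}: no such file")
    first = path.read_text().strip().splitlines()
    if not first:
        raise CurveParseError(f"{path}: empty cluster file")
    has_header = any(c.isalpha() for c in first[0])
    frame = pd.read_csv(path, header=0 if has_header else None, float_precision="round_trip")
    if frame.shape[1] != 2:
        raise CurveParseError(f"{path}: expected two columns (mean, variance)")
    frame.columns = ["mean", "variance"]
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        raise CurveParseError(f"{path}: non-numeric cluster rows")
    return ClusterSummary(numeric["mean"].to_numpy(float), numeric["variance"].to_numpy(float))


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of one command run.

    Echoed verbatim into every output manifest so results are auditable.
    """

    model_variant: str = "full"
    noise_mode: str = "inferred"
    sigma_fixed: Optional[float] = None
    noise_bounds: Tuple[float, float] = (1e-3, 10.0)
    threshold: Optional[float] = None
    tail_sd: float = 0.05
    priors: Dict[str, Dict[str, float]] = field(default_factory=dict)
    cluster_file: Optional[str] = None
    cluster_prior_kind: str = "gaussian"
    n_live: int = 100
    max_mcmc_steps: int = 20
    termination_tolerance: float = 1e-6
    max_iterations: int = 200_000
    seed: int = 0

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(self.noise_mode, self.sigma_fixed, tuple(self.noise_bounds))

    def ns_config(self, seed: Optional[int] = None) -> NSConfig:
        return NSConfig(
            n_live=self.n_live,
            max_mcmc_steps=self.max_mcmc_steps,
            termination_tolerance=self.termination_tolerance,
            max_iterations=self.max_iterations,
            seed=self.seed if seed is None else seed,
        )

    def prior_overrides(self) -> Dict[str, PriorEntry]:
        return {name: PriorEntry.from_dict(d) for name, d in self.priors.items()}

    def to_dict(self) -> Dict:
        return asdict(self)


_CONFIG_KEYS = set(RunConfig.__dataclass_fields__)
_SAMPLER_KEYS = {"n_live", "max_mcmc_steps", "termination_tolerance", "max_iterations"}


def load_config(path=None, overrides: Optional[Mapping] = None) -> RunConfig:
    """Load a YAML run configuration; unknown keys raise.

    Sampler fields may be given flat or under a ``sampler:`` section; prior
    overrides live under ``priors:`` as ``name: {kind, lower, upper, ...}``
    and round-trip exactly through :meth:`RunConfig.to_dict`.
    """
    raw: Dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        raw.update(loaded)
    sampler = raw.pop("sampler", None)
    if sampler:
        unknown = set(sampler) - _SAMPLER_KEYS - {"seed"}
        if unknown:
            raise ValueError(f"unknown sampler keys: {sorted(unknown)}")
        raw.update(sampler)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "noise_bounds" in raw:
        raw["noise_bounds"] = tuple(raw["noise_bounds"])
    cfg = RunConfig(**raw)
    cfg.noise_spec()  # validate
    cfg.ns_config()
    cfg.prior_overrides()
    return cfg


def config_digest(config: RunConfig) -> str:
    """Stable short digest of the effective configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
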