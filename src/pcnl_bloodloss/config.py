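"""YAML configuration for the analysis pipeline and the simulator."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .simulate import SyntheticCohortConfig

__all__ = ["AnalysisConfig", "load_config", "load_synthetic_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline-level knobs.

    ``hct_unit`` is the unit of hematocrit columns in input CSVs;
    ``final_timepoint`` is the endpoint of the blood-loss chain;
    ``product_hct`` the default transfused-product hematocrit fraction;
    ``adequacy_threshold`` the ±fractional deviation of transfused
    volume from TBL tolerated as adequate.
    """

    hct_unit: str = "percent"
    final_timepoint: str = "h72"
    product_hct: float = 1.0
    adequacy_threshold: float = 0.15

    def __post_init__(self) -> None:
        if self.hct_unit not in ("percent", "fraction"):
            raise ConfigError(f"hct_unit must be percent|fraction, got {self.hct_unit!r}")
        if self.final_timepoint not in ("h12", "h24", "h36", "h72"):
            raise ConfigError(f"invalid final_timepoint {self.final_timepoint!r}")
        if not (0.0 < self.product_hct <= 1.0):
            raise ConfigError("product_hct must be in (0, 1]")
        if not (0.0 <= self.adequacy_threshold < 1.0):
            raise ConfigError("adequacy_threshold must be in [0, 1)")


def _load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return data


def load_config(path) -> AnalysisConfig:
    """Load the analysis section (top-level keys or an ``analysis:`` block)."""
    data = _load_yaml(path)
    section = data.get("analysis", data)
    known = {f.name for f in fields(AnalysisConfig)}
    kwargs = {k: v for k, v in section.items() if k in known}
    try:
        return AnalysisConfig(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc


def load_synthetic_config(path, seed=None) -> SyntheticCohortConfig:
    """Load the ``synthetic:`` block (or top-level keys) of a YAML config."""
    data = _load_yaml(path)
    section = data.get("synthetic", data)
    known = {f.name for f in fields(SyntheticCohortConfig)}
    unknown = set(section) - known - {"analysis", "synthetic"}
    if unknown and "synthetic" in data:
        raise ConfigError(f"unknown synthetic config keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in section.items() if k in known}
    for tuple_key in ("pattern_split", "baseline_hct_range_percent"):
        if tuple_key in kwargs:
            kwargs[tuple_key] = tuple(kwargs[tuple_key])
    if seed is not None:
        kwargs["seed"] = seed
    try:
        return SyntheticCohortConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
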