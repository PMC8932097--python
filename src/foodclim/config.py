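"""Pipeline configuration: schema-validated YAML with documented defaults.

Every section maps onto a parameter dataclass; unknown keys are rejected so
typos fail loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .synthetic import ClimateGenParams, PanelGenParams, DEFAULT_ITEM_THRESHOLDS


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class SurveyConfig:
    respondents_per_region: int = 800
    item_thresholds: tuple[float, ...] = DEFAULT_ITEM_THRESHOLDS
    dialect: str = "item"

    def __post_init__(self):
        if self.dialect not in ("item", "rawscore"):
            raise ConfigError(f"unknown scoring dialect {self.dialect!r}")
        if self.respondents_per_region < 1:
            raise ConfigError("respondents_per_region must be >= 1")


@dataclass(frozen=True)
class IndicatorConfig:
    baseline: tuple[int, int] = (1981, 2010)
    spi_scale_months: int = 6
    spi_threshold: float = -1.5
    spi_calibration: tuple[int, int] | None = None  # defaults to baseline

    @property
    def calibration_window(self) -> tuple[int, int]:
        return self.spi_calibration or self.baseline


@dataclass(frozen=True)
class RegressionConfig:
    spec: str = "tvc"  # tvc | constant | binned-tvc | binned-constant
    cov: str = "cluster"  # cluster | hc1 | classical

    def __post_init__(self):
        if self.spec not in ("tvc", "constant", "binned-tvc", "binned-constant"):
            raise ConfigError(f"unknown regression spec {self.spec!r}")
        if self.cov not in ("cluster", "hc1", "classical"):
            raise ConfigError(f"unknown covariance {self.cov!r}")


@dataclass(frozen=True)
class AttributionConfig:
    n_groups: int = 4
    weights: str = "equal"  # equal | pop:<csv path>

    def __post_init__(self):
        if self.n_groups < 1:
            raise ConfigError("n_groups must be >= 1")
        if self.weights != "equal" and not self.weights.startswith("pop:"):
            raise ConfigError("weights must be 'equal' or 'pop:<csv>'")


_SECTION_TYPES = {
    "climate": ClimateGenParams,
    "panel": PanelGenParams,
    "survey": SurveyConfig,
    "indicators": IndicatorConfig,
    "regression": RegressionConfig,
    "attribution": AttributionConfig,
}


def _coerce(value: Any) -> Any:
    if isinstance(value, list):
        return tuple(_coerce(v) for v in value)
    return value


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {section!r}")
    try:
        return cls(**{k: _coerce(v) for k, v in data.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    climate: ClimateGenParams = field(default_factory=ClimateGenParams)
    panel: PanelGenParams = field(default_factory=PanelGenParams)
    survey: SurveyConfig = field(default_factory=SurveyConfig)
    indicators: IndicatorConfig = field(default_factory=IndicatorConfig)
    regression: RegressionConfig = field(default_factory=RegressionConfig)
    attribution: AttributionConfig = field(default_factory=AttributionConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        unknown = set(data) - set(_SECTION_TYPES) - {"seed"}
        if unknown:
            raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        seed = data.pop("seed", 0)
        if not isinstance(seed, int):
            raise ConfigError("seed must be an integer")
        kwargs["seed"] = seed
        for name, section_cls in _SECTION_TYPES.items():
            sect = data.get(name, {})
            if not isinstance(sect, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            kwargs[name] = _build_section(section_cls, sect, name)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(self, seed=seed)
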