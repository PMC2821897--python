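"""Run configuration: schema, validation, YAML/JSON loading."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .cohort import AgeExpenditureProfile, Cohort, CohortConfig, LifeTable
from .demand import DemandParams
from .model import Model, build_model
from .value_model import ICERDistributionSpec, ValueTierSchedule


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Anchors:
    """Printed totals the calibration reproduces."""

    pop_le_gain: float = 4.70
    uninsured_le_gain: float = 3.93
    strategy1_expenditure_delta: float = 72.0


@dataclass(frozen=True)
class RunConfig:
    distribution: ICERDistributionSpec = field(default_factory=ICERDistributionSpec)
    tiers: ValueTierSchedule = field(default_factory=ValueTierSchedule)
    demand: DemandParams = field(default_factory=DemandParams)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    anchors: Anchors = field(default_factory=Anchors)
    baseline_coinsurance: Optional[float] = None  # None -> calibrated
    unsuitable_fraction: float = 0.0
    pharmacy_scope_fraction: float = 0.10
    seed: int = 0
    output_dir: str = "results"

    def with_overrides(self, overrides: dict[str, Any]) -> "RunConfig":
        """Return a copy with dotted-path overrides applied,
        e.g. ``{"demand.elasticity": -0.23}``."""
        out = self
        for path, value in overrides.items():
            parts = path.split(".")
            if len(parts) == 1:
                out = dataclasses.replace(out, **{parts[0]: value})
            elif len(parts) == 2:
                section = getattr(out, parts[0])
                out = dataclasses.replace(
                    out, **{parts[0]: dataclasses.replace(section,
                                                          **{parts[1]: value})})
            else:
                raise ConfigError(f"override path too deep: {path}")
        return out


_SECTIONS = {
    "distribution": ICERDistributionSpec,
    "tiers": ValueTierSchedule,
    "demand": DemandParams,
    "cohort": CohortConfig,
    "anchors": Anchors,
}
_SCALARS = ("baseline_coinsurance", "unsuitable_fraction",
            "pharmacy_scope_fraction", "seed", "output_dir")


def _build_section(cls, data: dict, context: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context}: {exc}") from exc


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - set(_SECTIONS) - set(_SCALARS)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data[name]
            if not isinstance(section, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, section, name)
    for name in _SCALARS:
        if name in data:
            kwargs[name] = data[name]
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    """Load a YAML or JSON configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return config_from_dict(data)


def config_to_dict(config: RunConfig) -> dict:
    return dataclasses.asdict(config)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(config), indent=2))


def build_model_from_config(
    config: RunConfig,
    profile: Optional[AgeExpenditureProfile] = None,
    lifetable: Optional[LifeTable] = None,
) -> Model:
    """Calibrate the full model described by a :class:`RunConfig`."""
    cohort = Cohort(config.cohort, profile, lifetable)
    return build_model(
        config.distribution, config.tiers, config.demand, cohort,
        anchors={"pop_le_gain": config.anchors.pop_le_gain,
                 "uninsured_le_gain": config.anchors.uninsured_le_gain},
        baseline_coinsurance=config.baseline_coinsurance,
        strategy1_expenditure_delta=config.anchors.strategy1_expenditure_delta,
    )
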