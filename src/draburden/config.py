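"""Run configuration: parsing, validation, and round-trip serialization.

A run is fully described by one YAML file holding the base-year case count,
the growth anchors, the four transition rates, a set of named scenarios, the
uncertainty fraction, and bookkeeping (horizon, seed, output directory).
Every invariant violation is reported with the offending key so a bad config
can be fixed without reading tracebacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .population import GrowthAnchor
from .projection import TransitionRates
from .scenario import DeclineSchedule, ScenarioSpec

__all__ = ["RunConfig", "load_config", "dump_config", "packaged_config_path"]

_RATE_KEYS = ("incidence_major", "incidence_minor", "mortality_amputee", "mortality_nonamputee")
_SCHEDULE_KEYS = ("initial_multiplier", "period_years", "per_period_factor", "mode")


@dataclass(frozen=True)
class RunConfig:
    base_year: int
    base_count: float
    final_year: int
    anchors: tuple[GrowthAnchor, ...]
    rates: TransitionRates
    scenarios: Mapping[str, ScenarioSpec]
    scenario: str = "constant"
    uncertainty_fraction: float = 0.20
    output_dir: str = "out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in self.scenarios:
            raise ConfigurationError(
                f"scenario: selected scenario {self.scenario!r} is not defined in scenarios"
            )
        if not 0 <= self.uncertainty_fraction < 1:
            raise ConfigurationError("uncertainty_fraction: must lie in [0, 1)")

    @property
    def selected_scenario(self) -> ScenarioSpec:
        return self.scenarios[self.scenario]


def _require(mapping: Mapping[str, Any], key: str, context: str) -> Any:
    if key not in mapping:
        raise ConfigurationError(f"{context}{key}: missing required key")
    return mapping[key]


def _parse_schedule(raw: Any, context: str) -> DeclineSchedule | None:
    if raw is None or raw == "constant":
        return None
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"{context}: schedule must be a mapping or 'constant'")
    unknown = set(raw) - set(_SCHEDULE_KEYS)
    if unknown:
        raise ConfigurationError(f"{context}: unknown schedule keys {sorted(unknown)}")
    try:
        return DeclineSchedule(**raw)
    except ConfigurationError as exc:
        raise ConfigurationError(f"{context}: {exc}") from exc
    except TypeError as exc:
        raise ConfigurationError(f"{context}: {exc}") from exc


def _parse_scenario(name: str, raw: Any) -> ScenarioSpec:
    context = f"scenarios.{name}."
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"scenarios.{name}: must be a mapping")
    unknown = set(raw) - {"major", "minor"}
    if unknown:
        raise ConfigurationError(f"scenarios.{name}: unknown keys {sorted(unknown)}")
    return ScenarioSpec(
        name=name,
        major_schedule=_parse_schedule(raw.get("major"), context + "major"),
        minor_schedule=_parse_schedule(raw.get("minor"), context + "minor"),
    )


def _config_from_mapping(doc: Mapping[str, Any]) -> RunConfig:
    base_year = int(_require(doc, "base_year", ""))
    base_count = float(_require(doc, "base_count", ""))
    if base_count < 0:
        raise ConfigurationError("base_count: must be non-negative")

    raw_anchors = _require(doc, "anchors", "")
    if not isinstance(raw_anchors, list) or not raw_anchors:
        raise ConfigurationError("anchors: must be a non-empty list")
    anchors = []
    for i, a in enumerate(raw_anchors):
        ctx = f"anchors[{i}]."
        try:
            anchors.append(
                GrowthAnchor(
                    start_year=int(_require(a, "start_year", ctx)),
                    end_year=int(_require(a, "end_year", ctx)),
                    growth_percent=float(_require(a, "growth_percent", ctx)),
                )
            )
        except ConfigurationError as exc:
            raise ConfigurationError(f"anchors[{i}]: {exc}") from exc

    raw_rates = _require(doc, "rates", "")
    rate_values = {}
    for key in _RATE_KEYS:
        value = _require(raw_rates, key, "rates.")
        try:
            rate_values[key] = float(value)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"rates.{key}: not a number ({value!r})") from exc
    try:
        rates = TransitionRates(**rate_values)
    except ConfigurationError as exc:
        raise ConfigurationError(f"rates: {exc}") from exc

    raw_scenarios = doc.get("scenarios") or {"constant": {}}
    scenarios = {name: _parse_scenario(name, raw) for name, raw in raw_scenarios.items()}

    return RunConfig(
        base_year=base_year,
        base_count=base_count,
        final_year=int(doc.get("final_year", anchors[-1].end_year)),
        anchors=tuple(anchors),
        rates=rates,
        scenarios=scenarios,
        scenario=str(doc.get("scenario", next(iter(scenarios)))),
        uncertainty_fraction=float(doc.get("uncertainty_fraction", 0.20)),
        output_dir=str(doc.get("output_dir", "out")),
        seed=int(doc.get("seed", 0)),
    )


def load_config(path: str | Path) -> RunConfig:
    """Parse and fully validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"config file {path} is not valid YAML: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"config file {path} must hold a mapping at top level")
    return _config_from_mapping(doc)


def _schedule_to_doc(schedule: DeclineSchedule | None) -> Any:
    if schedule is None:
        return None
    return {
        "initial_multiplier": schedule.initial_multiplier,
        "period_years": schedule.period_years,
        "per_period_factor": schedule.per_period_factor,
        "mode": schedule.mode,
    }


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a RunConfig back to YAML; ``load_config`` of the result is identity."""
    doc: dict[str, Any] = {
        "base_year": config.base_year,
        "base_count": config.base_count,
        "final_year": config.final_year,
        "anchors": [
            {"start_year": a.start_year, "end_year": a.end_year, "growth_percent": a.growth_percent}
            for a in config.anchors
        ],
        "rates": {k: getattr(config.rates, k) for k in _RATE_KEYS},
        "scenarios": {
            name: {
                k: v
                for k, v in (
                    ("major", _schedule_to_doc(s.major_schedule)),
                    ("minor", _schedule_to_doc(s.minor_schedule)),
                )
                if v is not None
            }
            for name, s in config.scenarios.items()
        },
        "scenario": config.scenario,
        "uncertainty_fraction": config.uncertainty_fraction,
        "output_dir": config.output_dir,
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def packaged_config_path() -> Path:
    """Path of the Al-Ahsa 2022 example configuration shipped with the package."""
    return Path(resources.files("draburden").joinpath("data/alahsa_2022.yaml"))
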