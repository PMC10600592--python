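"""Annual-cycle projection engine.

Each calendar year is an independent modelling cycle: that year's diabetic
population is partitioned into major-amputation, minor-amputation, and
no-amputation states by the annual incidence rates, and two all-cause
mortality streams are computed — one over the year's incident amputees, one
over the non-amputees.  No state is carried between years; attrition of the
diabetic pool itself is assumed to be already reflected in the externally
supplied case series.

All arithmetic is kept unrounded.  The displayed total-amputation count is
the sum of the *rounded* major and minor counts (the convention the published
tables follow); every other displayed value is the rounded field itself, and
uncertainty bounds are always computed from unrounded values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

from .errors import ConfigurationError, DomainError
from .population import CaseSeries
from .uncertainty import round_half_up

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .scenario import ScenarioSpec

__all__ = ["TransitionRates", "YearProjection", "ProjectionSeries", "project_year", "run_projection"]


@dataclass(frozen=True)
class TransitionRates:
    """The four transition parameters of the model.

    Incidence rates are events per 100,000 diabetics per year; mortality
    rates are deaths per 1,000 person-years, applied separately to amputees
    and non-amputees.
    """

    incidence_major: float
    incidence_minor: float
    mortality_amputee: float
    mortality_nonamputee: float

    def __post_init__(self) -> None:
        for name in (
            "incidence_major",
            "incidence_minor",
            "mortality_amputee",
            "mortality_nonamputee",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.incidence_major + self.incidence_minor >= 100_000:
            raise ConfigurationError("combined incidence must be below 100,000 per 100,000")
        if self.mortality_amputee >= 1_000 or self.mortality_nonamputee >= 1_000:
            raise ConfigurationError("mortality rates must be below 1,000 per 1,000 person-years")

    def scaled(self, factor: float) -> "TransitionRates":
        """All four rates multiplied by a common factor (parameter-perturbation mode)."""
        return replace(
            self,
            incidence_major=self.incidence_major * factor,
            incidence_minor=self.incidence_minor * factor,
            mortality_amputee=self.mortality_amputee * factor,
            mortality_nonamputee=self.mortality_nonamputee * factor,
        )


@dataclass(frozen=True)
class YearProjection:
    """Unrounded state occupancies and death streams for one year."""

    year: int
    cases: float
    incident_major: float
    incident_minor: float
    deaths_amputee: float
    deaths_nonamputee: float

    @property
    def total_dra(self) -> float:
        return self.incident_major + self.incident_minor

    @property
    def non_amputees(self) -> float:
        return self.cases - self.total_dra

    @property
    def rounded_total_dra(self) -> int:
        """Display total: sum of the rounded components."""
        return round_half_up(self.incident_major) + round_half_up(self.incident_minor)


@dataclass(frozen=True)
class ProjectionSeries:
    """Ordered per-year projections over the modelling horizon."""

    years: tuple["YearProjection", ...]

    def __post_init__(self) -> None:
        ys = [p.year for p in self.years]
        if ys and ys != list(range(ys[0], ys[0] + len(ys))):
            raise ConfigurationError("projection years must be consecutive")

    def __iter__(self):
        return iter(self.years)

    def __len__(self) -> int:
        return len(self.years)

    def year(self, year: int) -> "YearProjection":
        first = self.years[0].year
        if not first <= year <= self.years[-1].year:
            raise KeyError(f"year {year} outside projection horizon")
        return self.years[year - first]


def project_year(cases: float, rates: TransitionRates, year: int = 0) -> YearProjection:
    """Distribute one year's diabetic population across the model states.

    ``incident_major = cases * incidence_major / 100,000`` and likewise for
    minor; amputee mortality applies to the year's incident amputation total,
    non-amputee mortality to the remainder.  Everything stays unrounded.
    """
    if cases < 0:
        raise DomainError(f"cases must be non-negative, got {cases}")
    incident_major = cases * rates.incidence_major / 100_000.0
    incident_minor = cases * rates.incidence_minor / 100_000.0
    total = incident_major + incident_minor
    return YearProjection(
        year=year,
        cases=cases,
        incident_major=incident_major,
        incident_minor=incident_minor,
        deaths_amputee=total * rates.mortality_amputee / 1_000.0,
        deaths_nonamputee=(cases - total) * rates.mortality_nonamputee / 1_000.0,
    )


def run_projection(
    series: CaseSeries,
    rates: TransitionRates,
    scenario: "ScenarioSpec | None" = None,
    base_year: int | None = None,
) -> ProjectionSeries:
    """Project every year of a case series under a scenario.

    Each year is computed independently from that year's unrounded case count
    and the scenario-adjusted rates; ``base_year`` (defaulting to the series
    start) anchors the scenario's decline schedules.
    """
    from .scenario import CONSTANT, effective_rates

    if scenario is None:
        scenario = CONSTANT
    if base_year is None:
        base_year = series.first_year
    projections = tuple(
        project_year(count, effective_rates(rates, scenario, year, base_year), year=year)
        for year, count in series
    )
    return ProjectionSeries(years=projections)
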