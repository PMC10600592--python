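"""Comparison of projected amputation totals with observed facility counts.

Validation is a single-year comparison: the model's projected amputation
total for a year against the total reported by the hospitals performing the
procedures.  Only totals are compared — facility reporting of the
major/minor split is typically incomplete — and interval containment is
inclusive at both bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .projection import YearProjection
from .uncertainty import UncertaintyInterval

__all__ = ["ObservedCounts", "ValidationResult", "compare", "read_observed_csv"]


@dataclass(frozen=True)
class ObservedCounts:
    """Amputation counts reported by each facility for one calendar year."""

    year: int
    facility_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for facility, count in self.facility_counts.items():
            if count < 0 or count != int(count):
                raise ConfigurationError(
                    f"facility {facility!r} count must be a non-negative integer, got {count}"
                )

    @property
    def total(self) -> int:
        return int(sum(self.facility_counts.values()))


@dataclass(frozen=True)
class ValidationResult:
    year: int
    projected: int
    observed: int
    difference: int  # projected - observed, signed
    within_ui: bool

    def __str__(self) -> str:
        sign = "+" if self.difference >= 0 else ""
        inside = "within" if self.within_ui else "outside"
        return (
            f"{self.year}: projected {self.projected} vs observed {self.observed} "
            f"({sign}{self.difference}; observed {inside} uncertainty interval)"
        )


def compare(
    projection: YearProjection,
    interval: UncertaintyInterval,
    observed: ObservedCounts,
) -> ValidationResult:
    """Projected-vs-observed comparison for one year.

    Returns the rounded projected total, the observed total, their signed
    difference, and whether the observed total lies inside the uncertainty
    interval (bounds inclusive).
    """
    if projection.year != observed.year:
        raise ValidationError(
            f"projection year {projection.year} does not match observed year {observed.year}"
        )
    projected = projection.rounded_total_dra
    obs_total = observed.total
    return ValidationResult(
        year=projection.year,
        projected=projected,
        observed=obs_total,
        difference=projected - obs_total,
        within_ui=interval.contains(obs_total),
    )


def read_observed_csv(path: str | Path, year: int | None = None) -> ObservedCounts:
    """Load observed counts from a (year, facility, count) CSV.

    With multiple years present, ``year`` selects one; with a single year it
    may be omitted.
    """
    df = pd.read_csv(path)
    required = {"year", "facility", "count"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"observed CSV must have columns {sorted(required)}")
    if year is None:
        years = df["year"].unique()
        if len(years) != 1:
            raise ConfigurationError("observed CSV holds multiple years; specify one")
        year = int(years[0])
    sub = df[df["year"] == year]
    if sub.empty:
        raise ConfigurationError(f"no observed rows for year {year}")
    return ObservedCounts(
        year=int(year),
        facility_counts={str(r.facility): int(r.count) for r in sub.itertuples()},
    )
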