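"""Time-varying incidence multipliers for scenario analysis.

A scenario scales the amputation incidence rates (never the mortality rates)
by a year-dependent multiplier.  A :class:`DeclineSchedule` describes a
multiplicative decline: an initial multiplier applied at the base year and a
per-period survival factor (0.8 for a 20% decline per period).  Three
compounding modes are supported:

``annualized``
    Geometric compounding at the per-period rate,
    ``m(y) = m0 * f ** ((y - y0) / p)``.
``stepwise``
    The multiplier drops only at whole periods,
    ``m(y) = m0 * f ** floor((y - y0) / p)``.
``interpolated``
    Straight-line interpolation between the whole-period values
    ``m0 * f ** k`` at years ``y0 + k * p`` — the natural form when a
    spreadsheet fills intermediate years linearly.

All three agree exactly at whole-period years.  A schedule of ``None`` in a
:class:`ScenarioSpec` means the constant scenario (multiplier 1 every year).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .errors import ConfigurationError, DomainError
from .projection import TransitionRates

__all__ = ["DeclineSchedule", "ScenarioSpec", "multiplier_at", "effective_rates", "MODES"]

MODES = ("annualized", "stepwise", "interpolated")


@dataclass(frozen=True)
class DeclineSchedule:
    initial_multiplier: float = 1.0
    period_years: int = 3
    per_period_factor: float = 1.0
    mode: str = "annualized"

    def __post_init__(self) -> None:
        if not 0 < self.initial_multiplier <= 1:
            raise ConfigurationError(
                f"initial_multiplier must lie in (0, 1], got {self.initial_multiplier}"
            )
        if not 0 < self.per_period_factor <= 1:
            raise ConfigurationError(
                f"per_period_factor must lie in (0, 1], got {self.per_period_factor}"
            )
        if self.period_years < 1:
            raise ConfigurationError(f"period_years must be >= 1, got {self.period_years}")
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    """Named pair of schedules for the major and minor incidence rates.

    ``None`` for a schedule means that rate is held constant (multiplier 1).
    """

    name: str
    major_schedule: Optional[DeclineSchedule] = None
    minor_schedule: Optional[DeclineSchedule] = None

    @property
    def is_constant(self) -> bool:
        return self.major_schedule is None and self.minor_schedule is None


CONSTANT = ScenarioSpec(name="constant")


def multiplier_at(schedule: Optional[DeclineSchedule], year: int, base_year: int) -> float:
    """Incidence multiplier of a schedule at a calendar year.

    Raises :class:`DomainError` for years before the base year; the result is
    always in (0, 1].
    """
    if year < base_year:
        raise DomainError(f"year {year} precedes base year {base_year}")
    if schedule is None:
        return 1.0
    t = (year - base_year) / schedule.period_years
    m0, f = schedule.initial_multiplier, schedule.per_period_factor
    if schedule.mode == "annualized":
        return m0 * f**t
    if schedule.mode == "stepwise":
        return m0 * f ** math.floor(t)
    # interpolated: linear between the stepwise knots
    k = math.floor(t)
    lo, hi = m0 * f**k, m0 * f ** (k + 1)
    return lo + (hi - lo) * (t - k)


def effective_rates(
    rates: TransitionRates, scenario: ScenarioSpec, year: int, base_year: int
) -> TransitionRates:
    """Transition rates with the scenario's incidence multipliers applied.

    Mortality rates pass through unchanged in every scenario.
    """
    return replace(
        rates,
        incidence_major=rates.incidence_major
        * multiplier_at(scenario.major_schedule, year, base_year),
        incidence_minor=rates.incidence_minor
        * multiplier_at(scenario.minor_schedule, year, base_year),
    )
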