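"""Synthetic inputs for end-to-end testing without any external data.

The projection itself is deterministic, so the synthetic layer supplies
(a) random but invariant-respecting transition-rate sets and growth anchors,
and (b) the one canonically stochastic piece of the problem: observed
facility counts.  Observation is modelled as a Poisson draw around the
model's unrounded amputation total scaled by a reporting-completeness
fraction (hospitals outside the reporting network make the observed total an
undercount), split across facilities by a multinomial.

All randomness flows from the explicit seed in :class:`SyntheticConfig`;
there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .population import GrowthAnchor
from .projection import TransitionRates, YearProjection
from .validation import ObservedCounts

__all__ = ["SyntheticConfig", "gen_rates", "gen_observed", "gen_anchors"]

# (low, high) sampling bounds per rate; units as in TransitionRates
DEFAULT_RATE_RANGES: dict[str, tuple[float, float]] = {
    "incidence_major": (50.0, 200.0),
    "incidence_minor": (80.0, 300.0),
    "mortality_amputee": (40.0, 150.0),
    "mortality_nonamputee": (10.0, 40.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    rate_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATE_RANGES)
    )
    n_facilities: int = 2
    reporting_completeness: float = 1.0
    facility_shares: tuple[float, ...] | None = None
    base_year: int = 2022
    base_count_range: tuple[float, float] = (20_000.0, 120_000.0)
    n_anchors: int = 2
    anchor_span_years: tuple[int, int] = (5, 15)
    growth_percent_range: tuple[float, float] = (100.0, 160.0)

    def __post_init__(self) -> None:
        for name, (low, high) in self.rate_ranges.items():
            if name not in DEFAULT_RATE_RANGES:
                raise ConfigurationError(f"unknown rate name {name!r} in rate_ranges")
            if not 0 <= low <= high:
                raise ConfigurationError(f"rate_ranges[{name!r}] must satisfy 0 <= low <= high")
        for name, (low, high) in self.rate_ranges.items():
            limit = 100_000.0 if name.startswith("incidence") else 1_000.0
            if high >= limit:
                raise ConfigurationError(f"rate_ranges[{name!r}] upper bound exceeds {limit}")
        if self.n_facilities < 1:
            raise ConfigurationError("n_facilities must be >= 1")
        if not 0 <= self.reporting_completeness <= 1:
            raise ConfigurationError(
                f"reporting_completeness must lie in [0, 1], got {self.reporting_completeness}"
            )
        if self.facility_shares is not None:
            if len(self.facility_shares) != self.n_facilities:
                raise ConfigurationError("facility_shares length must equal n_facilities")
            if any(s < 0 for s in self.facility_shares):
                raise ConfigurationError("facility_shares must be non-negative")
            if abs(sum(self.facility_shares) - 1.0) > 1e-9:
                raise ConfigurationError("facility_shares must sum to 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def shares(self) -> np.ndarray:
        if self.facility_shares is not None:
            return np.asarray(self.facility_shares, dtype=float)
        return np.full(self.n_facilities, 1.0 / self.n_facilities)


def gen_rates(config: SyntheticConfig, rng: np.random.Generator | None = None) -> TransitionRates:
    """Draw a transition-rate set uniformly from the configured ranges."""
    rng = config.rng() if rng is None else rng
    drawn = {
        name: float(rng.uniform(low, high)) for name, (low, high) in config.rate_ranges.items()
    }
    return TransitionRates(**drawn)


def gen_observed(
    projection: YearProjection,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> ObservedCounts:
    """Poisson-sampled observed facility counts around a projected year.

    The observed total is Poisson with mean
    ``unrounded total amputations x reporting_completeness``, split across
    facilities by a multinomial with the configured shares.
    """
    rng = config.rng() if rng is None else rng
    mean = projection.total_dra * config.reporting_completeness
    if mean < 0:
        raise ConfigurationError("projected total must be non-negative")
    total = int(rng.poisson(mean))
    split = rng.multinomial(total, config.shares())
    return ObservedCounts(
        year=projection.year,
        facility_counts={f"facility_{i + 1}": int(c) for i, c in enumerate(split)},
    )


def gen_anchors(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[float, list[GrowthAnchor]]:
    """Draw a base count and contiguous growth anchors.

    Growth percentages are at least 100 (non-shrinking populations), matching
    the setting the projection targets.
    """
    rng = config.rng() if rng is None else rng
    base_count = float(rng.uniform(*config.base_count_range))
    anchors = []
    start = config.base_year
    lo_span, hi_span = config.anchor_span_years
    for _ in range(config.n_anchors):
        span = int(rng.integers(lo_span, hi_span + 1))
        growth = float(rng.uniform(*config.growth_percent_range))
        anchors.append(GrowthAnchor(start_year=start, end_year=start + span, growth_percent=growth))
        start += span
    return base_count, anchors
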