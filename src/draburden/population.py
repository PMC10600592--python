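"""Annual diabetes case-count series from growth-factor anchors.

The diabetic population entering the projection is not modelled
demographically.  It is anchored: a known base-year count plus published
period growth factors (ratio of end-year to start-year count, expressed as a
percentage, e.g. 131.7 means the count grows by a factor 1.317 over the
period).  Counts for the years between anchors are filled in by straight-line
interpolation in absolute counts.

Anchor end-point values are chained as unrounded products and the unrounded
values are carried into subsequent segments and into all downstream
arithmetic; rounding only ever happens at display time.  Rounding an anchor
before chaining would shift later end-points by a unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .uncertainty import round_half_up

__all__ = ["GrowthAnchor", "CaseSeries", "build_case_series"]


@dataclass(frozen=True)
class GrowthAnchor:
    """One growth period: the case count at ``end_year`` equals the count at
    ``start_year`` times ``growth_percent / 100``."""

    start_year: int
    end_year: int
    growth_percent: float

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ConfigurationError(
                f"anchor end_year {self.end_year} must exceed start_year {self.start_year}"
            )
        if not self.growth_percent > 0:
            raise ConfigurationError(
                f"anchor growth_percent must be positive, got {self.growth_percent}"
            )

    @property
    def factor(self) -> float:
        """Multiplicative growth over the period (131.7 -> 1.317)."""
        return self.growth_percent / 100.0


@dataclass(frozen=True)
class CaseSeries:
    """Per-year diabetic case counts for consecutive calendar years.

    Counts are non-negative reals kept unrounded; use :meth:`rounded` for the
    integer display view.
    """

    first_year: int
    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.counts) == 0:
            raise ConfigurationError("case series must contain at least one year")
        if any(c < 0 for c in self.counts):
            raise ConfigurationError("case counts must be non-negative")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.counts) - 1

    @property
    def years(self) -> range:
        return range(self.first_year, self.last_year + 1)

    def value(self, year: int) -> float:
        if not self.first_year <= year <= self.last_year:
            raise KeyError(f"year {year} outside series {self.first_year}-{self.last_year}")
        return self.counts[year - self.first_year]

    def rounded(self, year: int) -> int:
        return round_half_up(self.value(year))

    def __iter__(self) -> Iterator[tuple[int, float]]:
        return iter(zip(self.years, self.counts))

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        """Two-column table (year, cases) with the unrounded counts."""
        return pd.DataFrame({"year": list(self.years), "cases": list(self.counts)})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_case_series(
    base_year: int,
    base_count: float,
    anchors: Sequence[GrowthAnchor],
    final_year: int | None = None,
) -> CaseSeries:
    """Chain growth anchors from a base count and interpolate yearly values.

    Anchors must be contiguous: the first starts at ``base_year`` and each
    subsequent anchor starts where the previous one ends.  The value at each
    anchor end-year is the unrounded chained product of the growth factors
    times ``base_count``; years in between lie on the straight line joining
    the two unrounded end-point values.

    Parameters
    ----------
    base_year, base_count
        The anchor origin: a known case count in a known calendar year.
    anchors
        Ordered contiguous growth periods.
    final_year
        Optional check; if given it must equal the last anchor's end year.
    """
    if base_count < 0:
        raise ConfigurationError(f"base_count must be non-negative, got {base_count}")
    if not anchors:
        raise ConfigurationError("at least one growth anchor is required")
    expected_start = base_year
    for a in anchors:
        if a.start_year != expected_start:
            raise ConfigurationError(
                f"anchors are not contiguous: expected start_year {expected_start}, "
                f"got {a.start_year}"
            )
        expected_start = a.end_year
    if final_year is not None and final_year != anchors[-1].end_year:
        raise ConfigurationError(
            f"final_year {final_year} does not match last anchor end_year "
            f"{anchors[-1].end_year}"
        )
    if final_year is not None and final_year < base_year:
        raise ConfigurationError("final_year precedes base_year")

    counts: list[float] = []
    seg_start_value = float(base_count)
    for a in anchors:
        seg_end_value = seg_start_value * a.factor
        span = a.end_year - a.start_year
        # linear in absolute counts; the end-point of each segment is the
        # unrounded chained product, carried into the next segment
        years = np.arange(0, span)
        seg = seg_start_value + (seg_end_value - seg_start_value) * years / span
        counts.extend(float(v) for v in seg)
        seg_start_value = seg_end_value
    counts.append(seg_start_value)
    return CaseSeries(first_year=base_year, counts=tuple(counts))
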