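"""Output tables: wide per-year summary and long-format tidy export.

The wide table mirrors the published layout — one row per year with the five
projected quantities, each flanked by its lower/upper extremes bounds.  All
count columns are integers: points are rounded (the amputation total as the
sum of its rounded components), bounds come from the unrounded values.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .projection import ProjectionSeries, YearProjection
from .uncertainty import UncertaintyInterval, extremes, round_half_up

__all__ = [
    "year_intervals",
    "projection_frame",
    "tidy_frame",
    "write_projection_table",
    "write_tidy_table",
]

#: column stem -> attribute holding the unrounded value
_QUANTITIES = {
    "total_dra": "total_dra",
    "major_dra": "incident_major",
    "minor_dra": "incident_minor",
    "deaths_amp": "deaths_amputee",
    "deaths_nonamp": "deaths_nonamputee",
}


def year_intervals(
    projection: YearProjection, fraction: float = 0.20
) -> dict[str, UncertaintyInterval]:
    """Extremes intervals for every displayed quantity of one year."""
    out: dict[str, UncertaintyInterval] = {}
    for stem, attr in _QUANTITIES.items():
        point = projection.rounded_total_dra if stem == "total_dra" else None
        out[stem] = extremes(getattr(projection, attr), fraction, point=point)
    return out


def projection_frame(series: ProjectionSeries, fraction: float = 0.20) -> pd.DataFrame:
    """Wide integer table: year, cases, then (point, lo, hi) per quantity."""
    rows = []
    for p in series:
        intervals = year_intervals(p, fraction)
        row: dict[str, int] = {"year": p.year, "cases": round_half_up(p.cases)}
        for stem in _QUANTITIES:
            iv = intervals[stem]
            row[stem] = iv.point
            row[f"{stem}_lo"] = iv.lower
            row[f"{stem}_hi"] = iv.upper
        rows.append(row)
    columns = ["year", "cases"]
    for stem in _QUANTITIES:
        columns += [stem, f"{stem}_lo", f"{stem}_hi"]
    return pd.DataFrame(rows, columns=columns).astype(int) if rows else pd.DataFrame(
        columns=columns
    )


def tidy_frame(
    series: ProjectionSeries, scenario_name: str, fraction: float = 0.20
) -> pd.DataFrame:
    """Long format (year, quantity, scenario, value, lo, hi) for plotting front-ends."""
    records = []
    for p in series:
        intervals = year_intervals(p, fraction)
        for stem, iv in intervals.items():
            records.append(
                {
                    "year": p.year,
                    "quantity": stem,
                    "scenario": scenario_name,
                    "value": iv.point,
                    "lo": iv.lower,
                    "hi": iv.upper,
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["year", "quantity", "scenario", "value", "lo", "hi"]
    )


def write_projection_table(
    series: ProjectionSeries, path: str | Path, fraction: float = 0.20
) -> Path:
    path = Path(path)
    projection_frame(series, fraction).to_csv(path, index=False)
    return path


def write_tidy_table(
    series: ProjectionSeries, scenario_name: str, path: str | Path, fraction: float = 0.20
) -> Path:
    path = Path(path)
    tidy_frame(series, scenario_name, fraction).to_csv(path, index=False)
    return path
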