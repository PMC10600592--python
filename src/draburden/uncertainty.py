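"""Analysis-of-extremes uncertainty intervals and the display rounding rule.

The uncertainty method is deterministic: every model output is allowed to
fluctuate a fixed fraction (default 20%) above and below its base-case value.
Bounds are computed on the *unrounded* output and only then rounded — the
distinction matters at the integer edge (128.68 x 1.2 = 154.4 rounds to 154,
whereas 129 x 1.2 = 154.8 would round to 155).

A single rounding rule is used for every displayed integer in the package:
round half up (ties at .5 go upward), matching common spreadsheet rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError, DomainError

__all__ = ["round_half_up", "UncertaintyInterval", "extremes", "parameter_extremes_bounds"]


def round_half_up(x: float) -> int:
    """Round a non-negative real to the nearest integer, ties upward."""
    if x < 0:
        raise DomainError(f"round_half_up requires a non-negative value, got {x}")
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class UncertaintyInterval:
    """Rounded point estimate with rounded extremes bounds.

    ``lower = round((1 - fraction) * unrounded)`` and
    ``upper = round((1 + fraction) * unrounded)``; the unrounded base is not
    stored, only its rounded images.
    """

    point: int
    lower: int
    upper: int
    fraction: float = 0.20

    def __post_init__(self) -> None:
        if not self.lower <= self.point <= self.upper:
            raise ConfigurationError(
                f"interval bounds out of order: {self.lower} <= {self.point} <= {self.upper}"
            )

    def contains(self, value: float) -> bool:
        """Inclusive containment at both bounds."""
        return self.lower <= value <= self.upper


def extremes(
    unrounded_value: float, fraction: float = 0.20, point: int | None = None
) -> UncertaintyInterval:
    """Extremes interval around one unrounded model output.

    Parameters
    ----------
    unrounded_value
        The base-case output before display rounding.
    fraction
        Half-width as a fraction of the base value, in [0, 1).
    point
        Optional displayed point estimate to carry; defaults to the rounded
        base value.  (Composite quantities may display a point that is a sum
        of rounded components rather than the rounded sum.)
    """
    if unrounded_value < 0:
        raise DomainError(f"extremes requires a non-negative value, got {unrounded_value}")
    if not 0 <= fraction < 1:
        raise ConfigurationError(f"extremes fraction must lie in [0, 1), got {fraction}")
    if point is None:
        point = round_half_up(unrounded_value)
    return UncertaintyInterval(
        point=point,
        lower=round_half_up(unrounded_value * (1.0 - fraction)),
        upper=round_half_up(unrounded_value * (1.0 + fraction)),
        fraction=fraction,
    )


def parameter_extremes_bounds(cases: float, rates, fraction: float = 0.20):
    """Alternative, non-default extremes mode: perturb the transition rates.

    Every rate is moved the full fraction down and up simultaneously and the
    envelope of the resulting single-year outputs is returned as
    ``(low YearProjection, high YearProjection)``.  Because the model is
    monotone increasing in each rate (non-amputee deaths excepted only at
    extreme incidence), the envelope is attained at the all-low and all-high
    corners.  This is *not* the mode used for the published-style tables —
    those apply the fraction to outputs, not inputs.
    """
    from .projection import project_year

    lo_rates = rates.scaled(1.0 - fraction)
    hi_rates = rates.scaled(1.0 + fraction)
    return project_year(cases, lo_rates), project_year(cases, hi_rates)
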