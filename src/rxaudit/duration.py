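"""Calculated duration and written-vs-calculated classification.

The calculated duration is the number of days a dispensed tablet supply
lasts when taken at the maximum prescribed dose and frequency:

    calculated = ((quantity x strength) / max dose per administration)
                 / administrations per day

i.e. the total number of possible administrations divided by the daily
administration rate.  It is exact and may be fractional; a partial final
administration contributes fractional time (supply-exhaustion convention).
Because ranged doses and PRN frequencies resolve upstream to their
maxima, this is the shortest duration consistent with the sig.

``consumption_oracle`` re-derives the same quantity by stepwise simulated
consumption and exists purely as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from typing import Optional

__all__ = [
    "RelationshipCategory",
    "DurationComparison",
    "DEFAULT_TOLERANCE_DAYS",
    "calculated_duration",
    "classify",
    "consumption_oracle",
]

#: Equality tolerance in days.  Effectively exact on rational inputs:
#: a fractional calculated duration (e.g. 2.5 d) never classifies as
#: EQUAL against an integer written duration.  Configurable for
#: sensitivity analysis.
DEFAULT_TOLERANCE_DAYS = 1e-9


class RelationshipCategory(str, Enum):
    """Three-way relationship between written and calculated durations."""

    EQUAL = "equal"
    CALC_GREATER = "calc_greater"
    CALC_LESS = "calc_less"


@dataclass(frozen=True)
class DurationComparison:
    """One prescription's written/calculated pair and its category."""

    rx_id: str
    written_duration_days: float
    calculated_duration_days: float
    category: RelationshipCategory
    ordered_at: datetime
    unit_converted: bool = False
    dose_was_range: bool = False


def calculated_duration(
    quantity: Optional[float],
    strength_mg: Optional[float],
    max_dose_mg: Optional[float],
    administrations_per_day: Optional[float],
) -> Optional[float]:
    """Days the dispensed supply lasts at maximum dose and frequency.

    Returns ``None`` when any input is absent or nonpositive; such
    records are counted as "calculated duration could not be computed"
    by the cohort pipeline.  No rounding is applied.
    """
    inputs = (quantity, strength_mg, max_dose_mg, administrations_per_day)
    if any(x is None or not x > 0 for x in inputs):
        return None
    total_doses = quantity * strength_mg / max_dose_mg
    return total_doses / administrations_per_day


def classify(
    written_days: float,
    calculated_days: float,
    tolerance: float = DEFAULT_TOLERANCE_DAYS,
) -> RelationshipCategory:
    """Classify a written/calculated pair.

    EQUAL when the two agree within ``tolerance``; CALC_GREATER when the
    supply outlasts the documented duration by more than the tolerance
    (the guideline-contradicting direction); CALC_LESS otherwise.  The
    three categories partition all valid pairs.
    """
    if written_days < 0:
        raise ValueError(f"written duration must be nonnegative, got {written_days}")
    diff = calculated_days - written_days
    if abs(diff) <= tolerance:
        return RelationshipCategory.EQUAL
    if diff > tolerance:
        return RelationshipCategory.CALC_GREATER
    return RelationshipCategory.CALC_LESS


def consumption_oracle(
    quantity: float,
    tablets_per_administration: float,
    administrations_per_day: float,
) -> float:
    """Day-by-day consumption simulation of the dispensed supply.

    Consumes ``tablets_per_administration`` tablets at each scheduled
    administration; once fewer tablets remain than a full administration,
    the remainder contributes a proportional fraction of one
    administration interval.  Agrees with ``calculated_duration`` on all
    valid inputs — kept as an independent verification path, not a
    production one.
    """
    if not (quantity > 0 and tablets_per_administration > 0 and administrations_per_day > 0):
        raise ValueError("consumption oracle requires positive inputs")
    remaining = quantity
    administrations = 0
    # step one administration at a time; epsilon guards float drift on
    # fractional tablet counts
    while remaining >= tablets_per_administration - 1e-12:
        remaining -= tablets_per_administration
        administrations += 1
    partial = max(remaining, 0.0) / tablets_per_administration
    return (administrations + partial) / administrations_per_day
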