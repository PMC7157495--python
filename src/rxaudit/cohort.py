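"""Inclusion/exclusion cascade, pre/post split, and cohort tabulation.

The cascade applies in a fixed order, so every record leaves it exactly
once and the flow counts are mutually exclusive:

1. route is not oral, or formulation is not tablet  -> excluded
2. drug is on the excluded list (buprenorphine/methadone, substring,
   case-insensitive)                                -> excluded
3. no written duration documented                   -> excluded (counted
   separately from step 4)
4. written duration in a unit that cannot be converted to days
                                                    -> excluded
5. calculated duration not computable (unmapped frequency, unparseable
   dose, missing quantity/strength)                 -> excluded
6. ordered outside the configured study window      -> excluded

Survivors are classified written-vs-calculated and split at the
intervention boundary (strictly before = pre).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional, Sequence

import pandas as pd

from .duration import (
    DurationComparison,
    RelationshipCategory,
    calculated_duration,
    classify,
)
from .records import (
    FrequencyLexicon,
    NormalizedPrescription,
    PrescriptionRecord,
    normalize_record,
)
from .stats import round_half_up

__all__ = [
    "CohortFlow",
    "CategoryCounts",
    "NormalizationLog",
    "apply_inclusion",
    "normalize_records",
    "build_comparison_cohort",
    "split_periods",
    "monthly_volumes",
]


@dataclass
class CohortFlow:
    """Counts at each step of the inclusion/exclusion cascade.

    ``n_unit_converted`` counts surviving records whose written duration
    was converted from a non-day unit; it is informational, not an
    exclusion, and is therefore not part of the conservation identity
    n_total = n_final + all exclusion counts.
    """

    n_total: int = 0
    n_excluded_route_form: int = 0
    n_excluded_drug: int = 0
    n_missing_written_duration: int = 0
    n_excluded_nonconvertible_unit: int = 0
    n_unit_converted: int = 0
    n_uncomputable_calculated: int = 0
    n_excluded_out_of_window: int = 0
    n_final: int = 0
    n_pre: int = 0
    n_post: int = 0

    @property
    def exclusions_total(self) -> int:
        return (
            self.n_excluded_route_form
            + self.n_excluded_drug
            + self.n_missing_written_duration
            + self.n_excluded_nonconvertible_unit
            + self.n_uncomputable_calculated
            + self.n_excluded_out_of_window
        )

    def check_conservation(self) -> None:
        if self.n_total != self.n_final + self.exclusions_total:
            raise AssertionError(
                f"flow conservation violated: total {self.n_total} != "
                f"final {self.n_final} + exclusions {self.exclusions_total}"
            )
        if self.n_final != self.n_pre + self.n_post:
            raise AssertionError("pre/post split does not partition the final cohort")

    def to_frame(self) -> pd.DataFrame:
        """One-row-per-step table mirroring the cohort flow diagram."""
        steps = [
            ("total prescriptions", self.n_total),
            ("excluded: non-oral route or non-tablet formulation", self.n_excluded_route_form),
            ("excluded: buprenorphine/methadone", self.n_excluded_drug),
            ("excluded: no written duration documented", self.n_missing_written_duration),
            ("excluded: written duration unit not convertible to days", self.n_excluded_nonconvertible_unit),
            ("excluded: calculated duration not computable", self.n_uncomputable_calculated),
            ("excluded: ordered outside study window", self.n_excluded_out_of_window),
            ("final comparison cohort", self.n_final),
            ("preintervention period", self.n_pre),
            ("postintervention period", self.n_post),
            ("(info) written duration converted from non-day units", self.n_unit_converted),
        ]
        return pd.DataFrame(steps, columns=["step", "count"])


@dataclass(frozen=True)
class CategoryCounts:
    """Relationship-category tallies for one cohort (or period)."""

    n: int
    equal: int
    calc_greater: int
    calc_less: int

    def __post_init__(self) -> None:
        if self.equal + self.calc_greater + self.calc_less != self.n:
            raise ValueError("category counts must sum to the cohort size")

    def count(self, category: RelationshipCategory) -> int:
        return {
            RelationshipCategory.EQUAL: self.equal,
            RelationshipCategory.CALC_GREATER: self.calc_greater,
            RelationshipCategory.CALC_LESS: self.calc_less,
        }[category]

    @classmethod
    def tally(cls, comparisons: Iterable[DurationComparison]) -> "CategoryCounts":
        eq = gt = lt = 0
        for c in comparisons:
            if c.category is RelationshipCategory.EQUAL:
                eq += 1
            elif c.category is RelationshipCategory.CALC_GREATER:
                gt += 1
            else:
                lt += 1
        return cls(n=eq + gt + lt, equal=eq, calc_greater=gt, calc_less=lt)


@dataclass
class NormalizationLog:
    """Diagnostics accumulated while normalizing: nothing is silently dropped."""

    unmapped_frequency_labels: dict[str, int] = field(default_factory=dict)
    dose_parse_failures: list[str] = field(default_factory=list)
    malformed_rows: list[str] = field(default_factory=list)

    def to_lines(self) -> list[str]:
        lines = [
            f"unmapped frequency label {label!r}: {count} records"
            for label, count in sorted(self.unmapped_frequency_labels.items())
        ]
        lines += [f"dose parse failure: {msg}" for msg in self.dose_parse_failures]
        lines += [f"malformed row: {msg}" for msg in self.malformed_rows]
        return lines


def _is_oral_tablet(record: PrescriptionRecord) -> bool:
    return (
        record.route.strip().lower() == "oral"
        and record.formulation.strip().lower() == "tablet"
    )


def apply_inclusion(
    records: Sequence[PrescriptionRecord],
    excluded_drugs: Sequence[str] = ("buprenorphine", "methadone"),
) -> tuple[list[PrescriptionRecord], CohortFlow]:
    """Apply the route/formulation and drug-name exclusions.

    Oral tablets only; buprenorphine and methadone are excluded by
    case-insensitive substring match on the drug name, since those agents
    are routinely used for opioid use disorder rather than analgesia.
    """
    flow = CohortFlow(n_total=len(records))
    drugs = tuple(d.lower() for d in excluded_drugs)
    included: list[PrescriptionRecord] = []
    for record in records:
        if not _is_oral_tablet(record):
            flow.n_excluded_route_form += 1
            continue
        name = record.drug_name.lower()
        if any(d in name for d in drugs):
            flow.n_excluded_drug += 1
            continue
        included.append(record)
    return included, flow


def normalize_records(
    records: Sequence[PrescriptionRecord],
    lexicon: Optional[FrequencyLexicon] = None,
    log: Optional[NormalizationLog] = None,
) -> tuple[list[NormalizedPrescription], NormalizationLog]:
    """Normalize each record's sig, logging unmapped labels and parse failures."""
    if lexicon is None:
        lexicon = FrequencyLexicon.default()
    if log is None:
        log = NormalizationLog()
    normalized = []
    for record in records:
        norm = normalize_record(record, lexicon)
        if record.frequency_label and norm.administrations_per_day is None:
            key = record.frequency_label.strip()
            log.unmapped_frequency_labels[key] = log.unmapped_frequency_labels.get(key, 0) + 1
        if record.discrete_dose and norm.max_dose_mg is None:
            log.dose_parse_failures.append(
                f"rx_id={record.rx_id}: {record.discrete_dose!r}"
            )
        normalized.append(norm)
    return normalized, log


def build_comparison_cohort(
    normalized: Sequence[NormalizedPrescription],
    flow: CohortFlow,
    tolerance: float = 1e-9,
    round_calculated: bool = False,
) -> tuple[list[DurationComparison], CohortFlow]:
    """Keep records with both durations; classify the relationship.

    Records lacking a written duration are dropped first (missing field
    vs nonconvertible unit counted separately), then records whose
    calculated duration cannot be computed.  ``round_calculated`` rounds
    the calculated duration to whole days before classification
    (sensitivity analysis; off by default).
    """
    comparisons: list[DurationComparison] = []
    for norm in normalized:
        record = norm.record
        if norm.written_duration_days is None:
            if record.written_duration_value is None or record.written_duration_unit is None:
                flow.n_missing_written_duration += 1
            else:
                flow.n_excluded_nonconvertible_unit += 1
            continue
        calc = calculated_duration(
            record.quantity,
            record.strength_mg,
            norm.max_dose_mg,
            norm.administrations_per_day,
        )
        if calc is None:
            flow.n_uncomputable_calculated += 1
            continue
        if norm.duration_unit_converted:
            flow.n_unit_converted += 1
        if round_calculated:
            calc = round_half_up(calc, 0)
            if calc == 0:
                calc = 1.0  # whole-day floor: a dispensed supply lasts at least one day
        comparisons.append(
            DurationComparison(
                rx_id=record.rx_id,
                written_duration_days=norm.written_duration_days,
                calculated_duration_days=calc,
                category=classify(norm.written_duration_days, calc, tolerance),
                ordered_at=record.ordered_at,
                unit_converted=norm.duration_unit_converted,
                dose_was_range=norm.dose_was_range,
            )
        )
    return comparisons, flow


def split_periods(
    comparisons: Sequence[DurationComparison],
    intervention_datetime: datetime,
    flow: Optional[CohortFlow] = None,
    study_start: Optional[datetime] = None,
    study_end: Optional[datetime] = None,
) -> tuple[CategoryCounts, CategoryCounts, CategoryCounts, list[DurationComparison]]:
    """Split the comparison cohort at the intervention boundary.

    Strictly before the boundary is pre; at or after is post.  Records
    outside the configured study window are excluded and counted.
    Returns (pre, post, pooled, in-window comparisons).
    """
    pre: list[DurationComparison] = []
    post: list[DurationComparison] = []
    out_of_window = 0
    for c in comparisons:
        if (study_start is not None and c.ordered_at < study_start) or (
            study_end is not None and c.ordered_at >= study_end
        ):
            out_of_window += 1
            continue
        (pre if c.ordered_at < intervention_datetime else post).append(c)
    pre_counts = CategoryCounts.tally(pre)
    post_counts = CategoryCounts.tally(post)
    pooled = CategoryCounts(
        n=pre_counts.n + post_counts.n,
        equal=pre_counts.equal + post_counts.equal,
        calc_greater=pre_counts.calc_greater + post_counts.calc_greater,
        calc_less=pre_counts.calc_less + post_counts.calc_less,
    )
    if flow is not None:
        flow.n_excluded_out_of_window += out_of_window
        flow.n_pre = pre_counts.n
        flow.n_post = post_counts.n
        flow.n_final = pooled.n
        flow.check_conservation()
    return pre_counts, post_counts, pooled, pre + post


def monthly_volumes(
    records: Sequence[PrescriptionRecord],
    study_start: datetime,
    study_end: datetime,
) -> tuple[pd.Series, pd.Series]:
    """Per-calendar-month prescription counts and per-patient-per-month counts.

    The monthly series covers every calendar month of the window
    (months with no prescriptions count zero); the per-patient series has
    one entry per (patient, month) pair with at least one prescription.
    Records outside the window are ignored here — they are excluded and
    counted by the cascade, not by this tabulation.
    """
    months = pd.period_range(start=study_start, end=study_end, freq="M")
    if len(months) and months[-1].to_timestamp() >= study_end:
        months = months[:-1]  # study_end is exclusive
    in_window = [r for r in records if study_start <= r.ordered_at < study_end]
    if not in_window:
        empty = pd.Series(0, index=months, dtype=int)
        return empty, pd.Series(dtype=int)
    df = pd.DataFrame(
        {
            "month": [pd.Period(r.ordered_at, freq="M") for r in in_window],
            "patient_id": [r.patient_id for r in in_window],
        }
    )
    per_month = df.groupby("month").size().reindex(months, fill_value=0)
    per_patient_month = df.groupby(["patient_id", "month"]).size()
    return per_month, per_patient_month
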