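"""Prescription data model and sig normalization.

A raw outpatient prescription row carries free-ish structured sig fields:
a frequency label (possibly PRN-marked), a discrete dose that may be a
range ("10-15 mg"), a dispense quantity in tablets, and a written
treatment duration with its own unit.  This module turns those into
computable quantities: administrations per 24-hour day, the maximum dose
per administration in mg (PRN and ranged doses are resolved to their
maximum, so downstream durations are the shortest consistent with the
sig), tablets per administration, and the written duration expressed in
days.

Absent or unparseable fields propagate as ``None`` and are counted by the
cohort pipeline; nothing is imputed at this layer.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "PrescriptionRecord",
    "FrequencyLexicon",
    "NormalizedPrescription",
    "DEFAULT_FREQUENCY_RATES",
    "DEFAULT_UNIT_FACTORS",
    "CSV_COLUMNS",
    "map_frequency",
    "resolve_max_dose",
    "convert_written_duration",
    "normalize_record",
    "records_from_dataframe",
    "read_prescriptions_csv",
    "records_to_dataframe",
]

#: Exact input CSV header, in order.  Empty string means absent.
CSV_COLUMNS = [
    "rx_id",
    "patient_id",
    "drug_name",
    "route",
    "formulation",
    "strength_mg",
    "discrete_dose",
    "frequency_label",
    "quantity",
    "written_duration_value",
    "written_duration_unit",
    "ordered_at",
    "is_refill",
]

#: Built-in frequency lexicon: canonical label -> administrations per
#: 24-hour day.  "every other day" class rates below 1 are legitimate.
#: User lexicon CSVs are merged over these defaults.
DEFAULT_FREQUENCY_RATES: dict[str, float] = {
    "daily": 1.0,
    "once a day": 1.0,
    "every 24 hours": 1.0,
    "qd": 1.0,
    "nightly": 1.0,
    "at bedtime": 1.0,
    "qhs": 1.0,
    "twice a day": 2.0,
    "two times a day": 2.0,
    "bid": 2.0,
    "three times a day": 3.0,
    "tid": 3.0,
    "four times a day": 4.0,
    "qid": 4.0,
    "every 3 hours": 8.0,
    "q3h": 8.0,
    "every 4 hours": 6.0,
    "q4h": 6.0,
    "every 6 hours": 4.0,
    "q6h": 4.0,
    "every 8 hours": 3.0,
    "q8h": 3.0,
    "every 12 hours": 2.0,
    "q12h": 2.0,
    "every other day": 0.5,
    "qod": 0.5,
    "weekly": 1.0 / 7.0,
    "once a week": 1.0 / 7.0,
}

#: Days per written-duration unit.  "doses" is handled separately because
#: it needs the administration rate.  Configurable; these are the defaults.
DEFAULT_UNIT_FACTORS: dict[str, float] = {
    "day": 1.0,
    "days": 1.0,
    "week": 7.0,
    "weeks": 7.0,
    "hour": 1.0 / 24.0,
    "hours": 1.0 / 24.0,
    "month": 30.0,
    "months": 30.0,
}

_DOSE_UNIT_NAMES = {"dose", "doses"}
_DAY_UNIT_NAMES = {"day", "days"}

# PRN markers stripped from the end of a frequency label; PRN never
# changes the rate (maximum-frequency convention for as-needed dosing).
_PRN_SUFFIXES = ("prn", "as needed", "as-needed")

_WS_RE = re.compile(r"\s+")

# "A mg" or "A-B mg" (hyphen or en dash), optional whitespace, optional
# decimal doses.  Anything else is a parse failure, never a guess.
_DOSE_RE = re.compile(
    r"^\s*(?P<lo>\d+(?:\.\d+)?)\s*(?:[-–]\s*(?P<hi>\d+(?:\.\d+)?))?\s*mg\s*$",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class PrescriptionRecord:
    """One raw outpatient prescription extract row."""

    rx_id: str
    patient_id: str
    drug_name: str
    route: str
    formulation: str
    strength_mg: Optional[float]
    discrete_dose: Optional[str]
    frequency_label: Optional[str]
    quantity: Optional[float]
    written_duration_value: Optional[float]
    written_duration_unit: Optional[str]
    ordered_at: datetime
    is_refill: bool

    def __post_init__(self) -> None:
        if self.strength_mg is not None and not self.strength_mg > 0:
            raise ValueError(f"strength_mg must be positive, got {self.strength_mg}")
        if self.quantity is not None and self.quantity < 0:
            raise ValueError(f"quantity must be nonnegative, got {self.quantity}")
        if self.written_duration_value is not None and self.written_duration_value < 0:
            raise ValueError(
                f"written_duration_value must be nonnegative, got {self.written_duration_value}"
            )


def _canonical(label: str) -> str:
    return _WS_RE.sub(" ", label.strip().lower())


@dataclass(frozen=True)
class FrequencyLexicon:
    """Mapping from canonical frequency label to administrations/day.

    Lookups are case-insensitive and whitespace-normalized.  When
    ``prn_suffix_rule`` is set (the default), a trailing PRN marker is
    stripped before lookup, so "twice a day PRN" resolves at the rate of
    "twice a day" — the maximum-frequency convention for as-needed
    prescriptions.
    """

    entries: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FREQUENCY_RATES))
    prn_suffix_rule: bool = True

    def __post_init__(self) -> None:
        canon = {}
        for label, rate in self.entries.items():
            rate = float(rate)
            if not rate > 0:
                raise ValueError(f"frequency rate must be positive: {label!r} -> {rate}")
            canon[_canonical(label)] = rate
        object.__setattr__(self, "entries", canon)

    @classmethod
    def default(cls) -> "FrequencyLexicon":
        return cls()

    @classmethod
    def from_csv(cls, path) -> "FrequencyLexicon":
        """Load a two-column ``label,rate`` CSV, merged over the defaults."""
        merged = dict(DEFAULT_FREQUENCY_RATES)
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            for i, row in enumerate(reader):
                if not row or (i == 0 and row[0].strip().lower() == "label"):
                    continue
                if len(row) < 2:
                    raise ValueError(f"lexicon row {i + 1} needs two columns: {row!r}")
                merged[row[0]] = float(row[1])
        return cls(entries=merged)

    def strip_prn(self, label: str) -> str:
        canon = _canonical(label)
        if self.prn_suffix_rule:
            for suffix in _PRN_SUFFIXES:
                if canon.endswith(suffix):
                    canon = canon[: -len(suffix)].rstrip()
                    break
        return canon

    def rate(self, label: Optional[str]) -> Optional[float]:
        if label is None or not label.strip():
            return None
        return self.entries.get(self.strip_prn(label))


@dataclass(frozen=True)
class NormalizedPrescription:
    """A prescription after sig normalization.

    Carries the four quantities the duration formula needs — dispensed
    tablets (on ``record``), maximum dose per administration, tablets per
    administration and administrations per day — plus the written duration
    converted to days.  Any of them may be absent; absent fields make the
    record uncomputable downstream.
    """

    record: PrescriptionRecord
    administrations_per_day: Optional[float]
    max_dose_mg: Optional[float]
    tablets_per_administration: Optional[float]
    written_duration_days: Optional[float]
    duration_unit_converted: bool = False
    dose_was_range: bool = False


def map_frequency(
    frequency_label: Optional[str], lexicon: Optional[FrequencyLexicon] = None
) -> Optional[float]:
    """Map a frequency label to administrations per 24-hour day.

    PRN marking never changes the rate ("twice a day PRN" == "twice a
    day"): for as-needed medications the maximum possible frequency is
    used.  Unknown or absent labels return ``None``; the record then
    counts as uncomputable rather than being guessed at.
    """
    if lexicon is None:
        lexicon = FrequencyLexicon.default()
    return lexicon.rate(frequency_label)


def resolve_max_dose(
    discrete_dose: Optional[str], strength_mg: Optional[float]
) -> Optional[tuple[float, float]]:
    """Resolve a discrete-dose string to (max dose mg, tablets/administration).

    A ranged dose "A-B mg" resolves to its top value B — the dispensed
    supply is consumed at the fastest rate the sig allows, making the
    calculated duration the shortest possible holding everything else
    fixed.  Returns ``None`` for absent inputs, unparseable text,
    inverted ranges, or nonpositive values.
    """
    if discrete_dose is None or strength_mg is None or not strength_mg > 0:
        return None
    m = _DOSE_RE.match(discrete_dose)
    if m is None:
        return None
    lo = float(m.group("lo"))
    hi = float(m.group("hi")) if m.group("hi") is not None else lo
    if not (0 < lo <= hi):
        return None
    return hi, hi / strength_mg


def convert_written_duration(
    value: Optional[float],
    unit: Optional[str],
    administrations_per_day: Optional[float] = None,
    unit_factors: Optional[Mapping[str, float]] = None,
) -> tuple[Optional[float], bool]:
    """Convert a written duration to days.

    Returns ``(days, converted)`` where ``converted`` flags that the unit
    was anything other than days.  Days pass through unchanged; weeks,
    hours and months use configurable factors (7, 1/24, 30 by default);
    a duration written as a number of doses divides by the administration
    rate and is therefore absent when the rate is unknown.  Unknown units
    yield ``(None, False)`` and are counted as nonconvertible downstream.
    """
    if value is None or unit is None:
        return None, False
    if value < 0:
        raise ValueError(f"written duration must be nonnegative, got {value}")
    factors = DEFAULT_UNIT_FACTORS if unit_factors is None else unit_factors
    canon = _canonical(unit)
    if canon in _DAY_UNIT_NAMES:
        return value, False
    if canon in _DOSE_UNIT_NAMES:
        if administrations_per_day is None or not administrations_per_day > 0:
            return None, False
        return value / administrations_per_day, True
    if canon in factors:
        return value * factors[canon], True
    return None, False


def normalize_record(
    record: PrescriptionRecord,
    lexicon: Optional[FrequencyLexicon] = None,
    unit_factors: Optional[Mapping[str, float]] = None,
) -> NormalizedPrescription:
    """Normalize one record's sig fields into computable quantities."""
    if lexicon is None:
        lexicon = FrequencyLexicon.default()
    rate = lexicon.rate(record.frequency_label)
    dose = resolve_max_dose(record.discrete_dose, record.strength_mg)
    max_dose_mg, tablets = (dose if dose is not None else (None, None))
    was_range = False
    if dose is not None:
        m = _DOSE_RE.match(record.discrete_dose)
        was_range = m is not None and m.group("hi") is not None
    days, converted = convert_written_duration(
        record.written_duration_value, record.written_duration_unit, rate, unit_factors
    )
    return NormalizedPrescription(
        record=record,
        administrations_per_day=rate,
        max_dose_mg=max_dose_mg,
        tablets_per_administration=tablets,
        written_duration_days=days,
        duration_unit_converted=converted,
        dose_was_range=was_range,
    )


# ---------------------------------------------------------------------------
# CSV / DataFrame interchange


def _opt_float(text: str) -> Optional[float]:
    text = text.strip()
    return float(text) if text else None


def _opt_str(text: str) -> Optional[str]:
    text = text.strip()
    return text if text else None


def records_from_dataframe(df: pd.DataFrame) -> tuple[list[PrescriptionRecord], list[str]]:
    """Build records from a schema DataFrame.

    All columns are read as text; empty strings mean absent.  Rows that
    violate field invariants (negative quantity, bad timestamp, ...) are
    returned as diagnostics, never silently dropped.
    """
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input is missing required columns: {', '.join(missing)}")
    records: list[PrescriptionRecord] = []
    problems: list[str] = []
    for row in df.itertuples(index=False):
        try:
            ordered_at = datetime.fromisoformat(str(row.ordered_at).strip())
            records.append(
                PrescriptionRecord(
                    rx_id=str(row.rx_id),
                    patient_id=str(row.patient_id),
                    drug_name=str(row.drug_name),
                    route=str(row.route),
                    formulation=str(row.formulation),
                    strength_mg=_opt_float(str(row.strength_mg)),
                    discrete_dose=_opt_str(str(row.discrete_dose)),
                    frequency_label=_opt_str(str(row.frequency_label)),
                    quantity=_opt_float(str(row.quantity)),
                    written_duration_value=_opt_float(str(row.written_duration_value)),
                    written_duration_unit=_opt_str(str(row.written_duration_unit)),
                    ordered_at=ordered_at,
                    is_refill=str(row.is_refill).strip().lower() in ("true", "1", "yes"),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"rx_id={getattr(row, 'rx_id', '?')}: {exc}")
    return records, problems


def read_prescriptions_csv(path) -> tuple[list[PrescriptionRecord], list[str]]:
    """Read the input CSV schema; returns (records, malformed-row diagnostics)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return records_from_dataframe(df)


def records_to_dataframe(records: Iterable[PrescriptionRecord]) -> pd.DataFrame:
    """Serialize records back to the exact input CSV schema."""
    rows = []
    for r in records:
        rows.append(
            {
                "rx_id": r.rx_id,
                "patient_id": r.patient_id,
                "drug_name": r.drug_name,
                "route": r.route,
                "formulation": r.formulation,
                "strength_mg": "" if r.strength_mg is None else _fmt(r.strength_mg),
                "discrete_dose": r.discrete_dose or "",
                "frequency_label": r.frequency_label or "",
                "quantity": "" if r.quantity is None else _fmt(r.quantity),
                "written_duration_value": ""
                if r.written_duration_value is None
                else _fmt(r.written_duration_value),
                "written_duration_unit": r.written_duration_unit or "",
                "ordered_at": r.ordered_at.isoformat(),
                "is_refill": "true" if r.is_refill else "false",
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))
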