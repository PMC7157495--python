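"""Seeded synthetic EHR prescription-extract generator.

Emulates a 22-month outpatient opioid prescription extract with a
pre/post intervention step change: monthly order volumes, a skewed
per-patient order distribution (median 1 order per patient-month,
IQR 1-2), ranged discrete doses, PRN frequency labels, refills, written
durations in mixed units, and the two corruption processes the audit
cares about — missing written durations (preferentially on refills) and
uncomputable calculated durations (preferentially on records that also
lack a written duration, as observed in practice).

The target written-vs-calculated relationship category of each clean
record is drawn first and the dispense quantity is then *solved* from it
by inverting the duration formula, so the pipeline can be validated
closed-loop: with corruption probabilities at zero, classification must
recover every record's intended category.

All randomness comes from one numpy Generator seeded once and consumed
in a fixed documented order (per record: contaminant flags, drug, dose
form, frequency, written duration, duration unit, refill, category,
quantity, corruption flags, timestamp), so a given seed is reproducible
across runs and configurations that share a prefix of the draw sequence.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional

import numpy as np

from .config import AuditConfig
from .duration import RelationshipCategory
from .records import PrescriptionRecord

__all__ = [
    "GeneratorConfig",
    "CategoryInfeasibleError",
    "generate",
    "quantity_for_category",
]

# (drug name, mg per tablet); names are illustrative, not a formulary
DEFAULT_DRUG_CATALOG: tuple[tuple[str, float], ...] = (
    ("oxycodone 5 mg tablet", 5.0),
    ("oxycodone 10 mg tablet", 10.0),
    ("oxycodone-acetaminophen 5-325 mg tablet", 5.0),
    ("hydrocodone-acetaminophen 5-325 mg tablet", 5.0),
    ("morphine 15 mg tablet", 15.0),
    ("hydromorphone 2 mg tablet", 2.0),
    ("tramadol 50 mg tablet", 50.0),
    ("codeine 30 mg tablet", 30.0),
)

DEFAULT_FREQUENCY_CATALOG: tuple[tuple[str, float], ...] = (
    ("every 4 hours", 0.14),
    ("every 6 hours", 0.26),
    ("every 8 hours", 0.10),
    ("twice a day", 0.18),
    ("three times a day", 0.14),
    ("four times a day", 0.08),
    ("daily", 0.07),
    ("every other day", 0.03),
)

#: Acute-pain-skewed written durations in days (3- and 7-day scripts dominate).
DEFAULT_WRITTEN_DURATION_WEIGHTS: dict[int, float] = {
    1: 0.06,
    2: 0.10,
    3: 0.30,
    5: 0.18,
    7: 0.22,
    10: 0.06,
    14: 0.06,
    30: 0.02,
}


class CategoryInfeasibleError(ValueError):
    """The requested category cannot be realized with whole-tablet rounding."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic extract.

    Defaults are a ~1/20 scale-down of a large two-hospital outpatient
    service (so the full pipeline runs in seconds) with the corruption
    rates and category mixes stepping at the intervention boundary.
    ``study_scale()`` returns the full-magnitude profile.  Volumes may
    differ pre vs post (``monthly_rx_mean_post``/``monthly_rx_sd_post``
    default to the pre values).
    """

    seed: int = 0
    study_start: datetime = datetime(2017, 10, 1)
    months_pre: int = 11
    months_post: int = 11
    monthly_rx_mean: float = 214.2
    monthly_rx_sd: float = 10.0
    monthly_rx_mean_post: Optional[float] = 206.1
    monthly_rx_sd_post: Optional[float] = 9.0
    n_patients: int = 1520
    p_missing_written_pre: float = 0.3354
    p_missing_written_post: float = 0.0945
    p_uncomputable_pre: float = 0.0601
    p_uncomputable_post: float = 0.0361
    p_ranged_dose: float = 0.045
    p_refill: float = 0.12
    p_prn: float = 0.6
    p_other_unit: float = 0.036
    p_unknown_unit: float = 0.002
    p_nonoral: float = 0.03
    p_excluded_drug: float = 0.01
    relationship_mix_pre: tuple[float, float, float] = (0.3886, 0.1795, 0.4319)
    relationship_mix_post: tuple[float, float, float] = (0.4435, 0.1621, 0.3944)
    written_duration_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_WRITTEN_DURATION_WEIGHTS)
    )
    drug_catalog: tuple[tuple[str, float], ...] = DEFAULT_DRUG_CATALOG
    frequency_catalog: tuple[tuple[str, float], ...] = DEFAULT_FREQUENCY_CATALOG
    #: how much likelier a refill is to lack a written duration
    refill_missing_weight: float = 5.0
    #: how much likelier a record missing its written duration is to also
    #: be uncomputable (the two defects co-occur in real extracts)
    uncomputable_missing_weight: float = 50.0

    def __post_init__(self) -> None:
        for name in (
            "p_missing_written_pre",
            "p_missing_written_post",
            "p_uncomputable_pre",
            "p_uncomputable_post",
            "p_ranged_dose",
            "p_refill",
            "p_prn",
            "p_other_unit",
            "p_unknown_unit",
            "p_nonoral",
            "p_excluded_drug",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        for name in ("relationship_mix_pre", "relationship_mix_post"):
            mix = getattr(self, name)
            if len(mix) != 3 or any(p < 0 for p in mix):
                raise ValueError(f"{name} must be three nonnegative probabilities")
            if abs(sum(mix) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1, got {sum(mix)}")
        if self.months_pre < 0 or self.months_post < 0:
            raise ValueError("month counts must be nonnegative")

    @classmethod
    def study_scale(cls, seed: int = 0) -> "GeneratorConfig":
        """Full-magnitude profile (tens of thousands of prescriptions)."""
        return cls(
            seed=seed,
            monthly_rx_mean=4284.64,
            monthly_rx_sd=200.68,
            monthly_rx_mean_post=4121.00,
            monthly_rx_sd_post=180.74,
            n_patients=30426,
        )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "GeneratorConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown generator config keys: {', '.join(sorted(unknown))}")
        kwargs = dict(mapping)
        if "study_start" in kwargs and not isinstance(kwargs["study_start"], datetime):
            kwargs["study_start"] = datetime.fromisoformat(str(kwargs["study_start"]))
        for key in ("relationship_mix_pre", "relationship_mix_post"):
            if key in kwargs:
                kwargs[key] = tuple(float(p) for p in kwargs[key])
        if "written_duration_weights" in kwargs:
            kwargs["written_duration_weights"] = {
                int(k): float(v) for k, v in kwargs["written_duration_weights"].items()
            }
        if "drug_catalog" in kwargs:
            kwargs["drug_catalog"] = tuple((str(n), float(s)) for n, s in kwargs["drug_catalog"])
        if "frequency_catalog" in kwargs:
            kwargs["frequency_catalog"] = tuple(
                (str(n), float(w)) for n, w in kwargs["frequency_catalog"]
            )
        return cls(**kwargs)

    @property
    def intervention_datetime(self) -> datetime:
        return _add_months(self.study_start, self.months_pre)

    @property
    def study_end(self) -> datetime:
        return _add_months(self.study_start, self.months_pre + self.months_post)

    def audit_config(self, **overrides) -> AuditConfig:
        """The matching audit window for data from this generator."""
        return AuditConfig(
            study_start=self.study_start,
            intervention_datetime=self.intervention_datetime,
            study_end=self.study_end,
            **overrides,
        )


def _add_months(start: datetime, months: int) -> datetime:
    month0 = start.year * 12 + (start.month - 1) + months
    return start.replace(year=month0 // 12, month=month0 % 12 + 1, day=1)


# built-in lexicon rates for the catalog labels (generator-side copy so a
# quantity can be solved without a normalization round-trip)
_CATALOG_RATES = {
    "every 4 hours": 6.0,
    "every 6 hours": 4.0,
    "every 8 hours": 3.0,
    "twice a day": 2.0,
    "three times a day": 3.0,
    "four times a day": 4.0,
    "daily": 1.0,
    "every other day": 0.5,
}

_CATEGORIES = (
    RelationshipCategory.EQUAL,
    RelationshipCategory.CALC_GREATER,
    RelationshipCategory.CALC_LESS,
)


def quantity_for_category(
    category: RelationshipCategory,
    written_days: float,
    tablets_per_administration: float,
    administrations_per_day: float,
    rng: np.random.Generator,
    tolerance: float = 1e-9,
) -> float:
    """Solve a dispense quantity that realizes the target category.

    Inverts the duration formula: the quantity that makes calculated ==
    written is ``written_days x tablets/administration x
    administrations/day``.  EQUAL returns that product exactly (possibly
    fractional — half-tablet scripts exist); CALC_GREATER scales it up by
    U(1.1, 3) and rounds up to a whole tablet; CALC_LESS scales down by
    U(0.3, 0.9) and rounds down with a one-tablet floor.  Rounding is
    re-verified against the target and redrawn if it flipped the
    category; a category no whole-tablet quantity can realize raises
    :class:`CategoryInfeasibleError`.
    """
    if not (written_days > 0 and tablets_per_administration > 0 and administrations_per_day > 0):
        raise ValueError("quantity_for_category requires positive inputs")
    daily_tablets = tablets_per_administration * administrations_per_day
    product = written_days * daily_tablets
    if category is RelationshipCategory.EQUAL:
        return product
    if category is RelationshipCategory.CALC_GREATER:
        for _ in range(32):
            q = math.ceil(product * rng.uniform(1.1, 3.0))
            if q / daily_tablets > written_days + tolerance:
                return float(q)
        return float(math.floor(product) + 1)
    # CALC_LESS: a single tablet is the smallest dispensable supply
    if 1.0 / daily_tablets >= written_days - tolerance:
        raise CategoryInfeasibleError(
            f"no whole-tablet quantity gives a duration below {written_days} d "
            f"at {daily_tablets} tablets/day"
        )
    for _ in range(32):
        q = max(1.0, float(math.floor(product * rng.uniform(0.3, 0.9))))
        if q / daily_tablets < written_days - tolerance:
            return q
    return max(1.0, float(math.ceil(product)) - 1.0)


def _month_span(anchor: datetime) -> float:
    return float(calendar.monthrange(anchor.year, anchor.month)[1])


def _stratified_probs(
    p_overall: float, p_stratum: float, weight: float
) -> tuple[float, float]:
    """Split an overall event rate across a flagged and unflagged stratum.

    The flagged stratum (fraction ``p_stratum`` of records) is ``weight``
    times likelier to show the event; rates are chosen so the expected
    overall rate equals ``p_overall`` exactly.  When the weighted rate
    would exceed 1 it is clamped and the remainder is pushed onto the
    unflagged stratum, preserving the overall target whenever it is
    attainable.
    """
    if p_overall <= 0:
        return 0.0, 0.0
    denom = p_stratum * weight + (1.0 - p_stratum)
    p_out = p_overall / denom
    p_in = weight * p_out
    if p_in > 1.0:
        p_in = 1.0
        if p_stratum < 1.0:
            p_out = (p_overall - p_stratum) / (1.0 - p_stratum)
        else:
            p_out = 0.0
    return min(1.0, p_in), min(1.0, max(0.0, p_out))


def generate(
    config: GeneratorConfig, return_truth: bool = False
) -> list[PrescriptionRecord] | tuple[list[PrescriptionRecord], dict[str, RelationshipCategory]]:
    """Generate a synthetic prescription extract; deterministic given seed.

    With ``return_truth=True`` also returns the intended relationship
    category of every clean in-scope record (contaminants and corrupted
    records carry no truth entry), for closed-loop validation.
    """
    rng = np.random.default_rng(config.seed)
    drug_names = [d[0] for d in config.drug_catalog]
    strengths = [d[1] for d in config.drug_catalog]
    freq_labels = [f[0] for f in config.frequency_catalog]
    freq_weights = np.array([f[1] for f in config.frequency_catalog], dtype=float)
    freq_weights /= freq_weights.sum()
    for label in freq_labels:
        if label not in _CATALOG_RATES:
            raise ValueError(f"frequency catalog label without a known rate: {label!r}")
    days_choices = np.array(sorted(config.written_duration_weights), dtype=float)
    days_weights = np.array(
        [config.written_duration_weights[int(d)] for d in days_choices], dtype=float
    )
    days_weights /= days_weights.sum()

    records: list[PrescriptionRecord] = []
    truth: dict[str, RelationshipCategory] = {}
    rx_serial = 0

    total_months = config.months_pre + config.months_post
    for month_idx in range(total_months):
        is_post = month_idx >= config.months_pre
        month_start = _add_months(config.study_start, month_idx)
        span_days = _month_span(month_start)
        if is_post and config.monthly_rx_mean_post is not None:
            mean = config.monthly_rx_mean_post
            sd = config.monthly_rx_sd_post if config.monthly_rx_sd_post is not None else config.monthly_rx_sd
        else:
            mean, sd = config.monthly_rx_mean, config.monthly_rx_sd
        n_month = int(round(max(0.0, rng.normal(mean, sd))))

        p_missing = config.p_missing_written_post if is_post else config.p_missing_written_pre
        p_unc = config.p_uncomputable_post if is_post else config.p_uncomputable_pre
        mix = np.asarray(
            config.relationship_mix_post if is_post else config.relationship_mix_pre
        )
        # per-stratum corruption rates preserving the period-level targets
        p_missing_refill, p_missing_nonrefill = _stratified_probs(
            p_missing, config.p_refill, config.refill_missing_weight
        )
        p_unc_missing, p_unc_written = _stratified_probs(
            p_unc, p_missing, config.uncomputable_missing_weight
        )

        # skewed patient assignment: geometric(0.6) orders per patient-month
        # puts >half the mass at a single order (median 1, IQR 1-2)
        patient_of: list[str] = []
        while len(patient_of) < n_month:
            pid = f"P{int(rng.integers(config.n_patients)):06d}"
            k = int(rng.geometric(0.6))
            patient_of.extend([pid] * min(k, n_month - len(patient_of)))

        for i in range(n_month):
            rx_serial += 1
            rx_id = f"RX{rx_serial:08d}"
            patient_id = patient_of[i]
            contaminant_route = rng.random() < config.p_nonoral
            contaminant_drug = rng.random() < config.p_excluded_drug
            drug_idx = int(rng.integers(len(drug_names)))
            drug_name, strength = drug_names[drug_idx], strengths[drug_idx]
            ranged = rng.random() < config.p_ranged_dose
            if ranged:
                low_tabs, tpa = 1.0, 2.0
                discrete_dose = f"{_fmt_mg(low_tabs * strength)}-{_fmt_mg(tpa * strength)} mg"
            else:
                tpa = 2.0 if rng.random() < 0.2 else 1.0
                discrete_dose = f"{_fmt_mg(tpa * strength)} mg"
            freq_idx = int(rng.choice(len(freq_labels), p=freq_weights))
            freq_label = freq_labels[freq_idx]
            apd = _CATALOG_RATES[freq_label]
            if rng.random() < config.p_prn:
                freq_label = freq_label + " PRN"
            written_days = float(rng.choice(days_choices, p=days_weights))
            unit_kind = rng.random()
            is_refill = rng.random() < config.p_refill
            category = _CATEGORIES[int(rng.choice(3, p=mix))]
            # redraw sig pieces until the category is feasible with whole tablets
            tries = 0
            while (
                category is RelationshipCategory.CALC_LESS
                and 1.0 / (tpa * apd) >= written_days - 1e-9
            ):
                tries += 1
                if tries > 100:
                    raise CategoryInfeasibleError("could not find a feasible sig")
                written_days = float(rng.choice(days_choices, p=days_weights))
                freq_idx = int(rng.choice(len(freq_labels), p=freq_weights))
                base = freq_labels[freq_idx]
                apd = _CATALOG_RATES[base]
                freq_label = base + " PRN" if freq_label.lower().endswith("prn") else base
            quantity = quantity_for_category(category, written_days, tpa, apd, rng)

            value: Optional[float] = written_days
            unit: Optional[str] = "days"
            if unit_kind < config.p_other_unit:
                alt = int(rng.integers(3))
                if alt == 0:
                    value, unit = written_days / 7.0, "weeks"
                elif alt == 1:
                    value, unit = written_days * 24.0, "hours"
                else:
                    value, unit = written_days * apd, "doses"
            elif unit_kind < config.p_other_unit + config.p_unknown_unit:
                unit = "courses"

            p_miss_here = p_missing_refill if is_refill else p_missing_nonrefill
            missing_written = rng.random() < p_miss_here
            p_unc_here = p_unc_missing if missing_written else p_unc_written
            uncomputable = rng.random() < p_unc_here
            unc_mechanism = int(rng.integers(3))
            ordered_at = month_start + timedelta(days=float(rng.uniform(0.0, span_days)))
            ordered_at = ordered_at.replace(microsecond=0)

            route, formulation = "oral", "tablet"
            if contaminant_route:
                route, formulation = (("buccal", "film"), ("oral", "solution"))[
                    int(rng.integers(2))
                ]
            if contaminant_drug:
                drug_name = ("methadone 10 mg tablet", "buprenorphine 2 mg tablet")[
                    int(rng.integers(2))
                ]
            if missing_written:
                value, unit = None, None
            q: Optional[float] = quantity
            dd: Optional[str] = discrete_dose
            fl: Optional[str] = freq_label
            if uncomputable:
                if unc_mechanism == 0:
                    q = None
                elif unc_mechanism == 1:
                    fl = "per instructions"
                else:
                    dd = None

            records.append(
                PrescriptionRecord(
                    rx_id=rx_id,
                    patient_id=patient_id,
                    drug_name=drug_name,
                    route=route,
                    formulation=formulation,
                    strength_mg=strength,
                    discrete_dose=dd,
                    frequency_label=fl,
                    quantity=q,
                    written_duration_value=value,
                    written_duration_unit=unit,
                    ordered_at=ordered_at,
                    is_refill=is_refill,
                )
            )
            clean = not (
                contaminant_route
                or contaminant_drug
                or missing_written
                or uncomputable
                or unit == "courses"
            )
            if clean:
                truth[rx_id] = category

    if return_truth:
        return records, truth
    return records


def _fmt_mg(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)
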