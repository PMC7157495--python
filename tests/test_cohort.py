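"""Inclusion cascade, flow conservation, period split, monthly volumes."""

from datetime import datetime

import pytest

from rxaudit.cohort import (
    CategoryCounts,
    CohortFlow,
    apply_inclusion,
    build_comparison_cohort,
    monthly_volumes,
    normalize_records,
    split_periods,
)
from rxaudit.duration import RelationshipCategory
from rxaudit.records import NormalizedPrescription

INTERVENTION = datetime(2018, 9, 1)


def run_cascade(records, **kwargs):
    included, flow = apply_inclusion(records)
    normalized, _ = normalize_records(included)
    return build_comparison_cohort(normalized, flow, **kwargs)


class TestApplyInclusion:
    def test_route_and_formulation_filter(self, make_record):
        records = [
            make_record(rx_id="A", route="buccal", formulation="film"),
            make_record(rx_id="B", route="oral", formulation="solution"),
            make_record(rx_id="C"),
        ]
        included, flow = apply_inclusion(records)
        assert [r.rx_id for r in included] == ["C"]
        assert flow.n_excluded_route_form == 2
        assert flow.n_excluded_drug == 0

    def test_opioid_use_disorder_drugs_excluded_by_substring(self, make_record):
        records = [
            make_record(rx_id="A", drug_name="Methadone HCl 10 mg tablet"),
            make_record(rx_id="B", drug_name="BUPRENORPHINE 2 mg tablet"),
            make_record(rx_id="C", drug_name="oxycodone 5 mg tablet"),
        ]
        included, flow = apply_inclusion(records)
        assert [r.rx_id for r in included] == ["C"]
        assert flow.n_excluded_drug == 2

    def test_route_filter_applies_before_drug_filter(self, make_record):
        # a doubly-defective record leaves the cascade at its first step
        records = [make_record(route="buccal", drug_name="methadone 10 mg tablet")]
        _, flow = apply_inclusion(records)
        assert flow.n_excluded_route_form == 1
        assert flow.n_excluded_drug == 0


class TestBuildComparisonCohort:
    def test_complete_records_all_survive(self, make_record):
        records = [make_record(rx_id=f"R{i}") for i in range(10)]
        comparisons, flow = run_cascade(records)
        assert len(comparisons) == 10
        assert flow.exclusions_total == 0

    def test_empty_input(self):
        comparisons, flow = run_cascade([])
        assert comparisons == [] and flow.n_total == 0

    def test_missing_vs_nonconvertible_counted_separately(self, make_record):
        records = [
            make_record(rx_id="A", written_duration_value=None, written_duration_unit=None),
            make_record(rx_id="B", written_duration_unit="courses"),
            make_record(rx_id="C"),
        ]
        comparisons, flow = run_cascade(records)
        assert flow.n_missing_written_duration == 1
        assert flow.n_excluded_nonconvertible_unit == 1
        assert [c.rx_id for c in comparisons] == ["C"]

    def test_uncomputable_counted(self, make_record):
        records = [
            make_record(rx_id="A", quantity=None),
            make_record(rx_id="B", frequency_label="see instructions"),
            make_record(rx_id="C", discrete_dose="one tab"),
            make_record(rx_id="D"),
        ]
        comparisons, flow = run_cascade(records)
        assert flow.n_uncomputable_calculated == 3
        assert [c.rx_id for c in comparisons] == ["D"]

    def test_unit_converted_flagged_and_counted(self, make_record):
        records = [make_record(written_duration_value=1.0, written_duration_unit="weeks")]
        comparisons, flow = run_cascade(records)
        assert flow.n_unit_converted == 1
        assert comparisons[0].written_duration_days == 7.0
        assert comparisons[0].unit_converted

    def test_rounding_option_changes_classification(self, make_record):
        # 9 tablets of a 1-tablet BID sig last 4.5 days against 5 written
        records = [make_record(quantity=9.0, written_duration_value=5.0)]
        exact, _ = run_cascade(records)
        rounded, _ = run_cascade(records, round_calculated=True)
        assert exact[0].category is RelationshipCategory.CALC_LESS
        assert rounded[0].category is RelationshipCategory.EQUAL

    def test_study_scale_exclusion_arithmetic(self, make_record):
        """A full-scale cohort built with known defect counts reproduces its
        inclusion arithmetic: 92,462 extracted, 20,098 without a written
        duration, 50 of the rest uncomputable, leaving 72,314."""
        total, missing, uncomputable = 92_462, 20_098, 50
        missing_rec = make_record(
            rx_id="M", written_duration_value=None, written_duration_unit=None
        )
        unc_rec = make_record(rx_id="U", quantity=None)
        good_rec = make_record(rx_id="G")

        def norm(rec, days):
            return NormalizedPrescription(
                record=rec,
                administrations_per_day=2.0,
                max_dose_mg=5.0,
                tablets_per_administration=1.0,
                written_duration_days=days,
            )

        normalized = (
            [norm(missing_rec, None)] * missing
            + [norm(unc_rec, 3.0)] * uncomputable
            + [norm(good_rec, 3.0)] * (total - missing - uncomputable)
        )
        flow = CohortFlow(n_total=total)
        comparisons, flow = build_comparison_cohort(normalized, flow)
        assert flow.n_missing_written_duration == missing
        assert flow.n_uncomputable_calculated == uncomputable
        assert len(comparisons) == 72_314
        pre, post, pooled, _ = split_periods(comparisons, INTERVENTION, flow)
        flow.check_conservation()
        assert flow.n_final == 72_314


class TestSplitPeriods:
    def test_boundary_is_strictly_before(self, make_record):
        records = [
            make_record(rx_id="pre", ordered_at=datetime(2018, 8, 31, 23, 59)),
            make_record(rx_id="post", ordered_at=datetime(2018, 9, 1, 0, 0)),
        ]
        comparisons, flow = run_cascade(records)
        pre, post, pooled, kept = split_periods(comparisons, INTERVENTION, flow)
        assert (pre.n, post.n) == (1, 1)
        assert pooled.n == 2

    def test_pooled_is_componentwise_sum(self, make_record):
        records = [
            make_record(rx_id=f"R{i}", ordered_at=datetime(2018, 3 + 2 * (i % 5), 5), quantity=q)
            for i, q in enumerate([6.0, 6.0, 4.0, 8.0, 6.0, 2.0, 12.0, 6.0])
        ]
        comparisons, flow = run_cascade(records)
        pre, post, pooled, _ = split_periods(comparisons, INTERVENTION, flow)
        assert pooled.equal == pre.equal + post.equal
        assert pooled.calc_greater == pre.calc_greater + post.calc_greater
        assert pooled.calc_less == pre.calc_less + post.calc_less
        flow.check_conservation()

    def test_out_of_window_excluded_and_counted(self, make_record):
        records = [
            make_record(rx_id="in", ordered_at=datetime(2018, 5, 1)),
            make_record(rx_id="early", ordered_at=datetime(2015, 1, 1)),
        ]
        comparisons, flow = run_cascade(records)
        pre, post, pooled, kept = split_periods(
            comparisons,
            INTERVENTION,
            flow,
            study_start=datetime(2017, 10, 1),
            study_end=datetime(2019, 8, 1),
        )
        assert flow.n_excluded_out_of_window == 1
        assert pooled.n == 1
        flow.check_conservation()

    def test_category_counts_must_sum(self):
        with pytest.raises(ValueError):
            CategoryCounts(n=5, equal=1, calc_greater=1, calc_less=1)


class TestMonthlyVolumes:
    def test_single_month_single_patient(self, make_record):
        records = [make_record(rx_id=f"R{i}", ordered_at=datetime(2018, 1, 10 + i)) for i in range(3)]
        per_month, per_patient = monthly_volumes(
            records, datetime(2018, 1, 1), datetime(2018, 2, 1)
        )
        assert list(per_month) == [3]
        assert list(per_patient) == [3]

    def test_uniform_volume_has_zero_sd(self, make_record):
        records = []
        start, end = datetime(2017, 10, 1), datetime(2019, 8, 1)
        for m in range(22):
            anchor = datetime(2017 + (9 + m) // 12, (9 + m) % 12 + 1, 15)
            records += [
                make_record(rx_id=f"R{m}-{i}", patient_id=f"P{i}", ordered_at=anchor)
                for i in range(10)
            ]
        per_month, per_patient = monthly_volumes(records, start, end)
        assert len(per_month) == 22
        assert per_month.mean() == 10.0
        assert per_month.std(ddof=1) == 0.0

    def test_empty_months_count_zero(self, make_record):
        records = [make_record(ordered_at=datetime(2018, 1, 10))]
        per_month, _ = monthly_volumes(records, datetime(2018, 1, 1), datetime(2018, 4, 1))
        assert list(per_month) == [1, 0, 0]
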