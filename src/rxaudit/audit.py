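"""The audit model: written-vs-calculated duration discrepancy, pre vs post.

``DurationAudit`` is built from a prescription extract (DataFrame or CSV)
plus an :class:`~rxaudit.config.AuditConfig`; ``fit()`` runs the full
cascade — inclusion filters, sig normalization, duration computation,
classification, pre/post split — and returns an :class:`AuditResults`
carrying the cohort flow, per-period category counts, proportion
estimates with 95% CIs, and the comparison tests (per-category and
omnibus chi-squares, monthly-volume t test, per-patient rank-sum), with
a ``summary()`` table mirroring the audit's headline layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__ as _version
from .cohort import (
    CategoryCounts,
    CohortFlow,
    NormalizationLog,
    apply_inclusion,
    build_comparison_cohort,
    monthly_volumes,
    normalize_records,
    split_periods,
)
from .config import AuditConfig
from .duration import RelationshipCategory, calculated_duration
from .records import FrequencyLexicon, PrescriptionRecord, records_from_dataframe
from .stats import (
    ProportionEstimate,
    TestResult,
    chi_square_table,
    proportion_ci,
    round_half_up,
    t_test_means,
    two_proportion_test,
    wilcoxon_rank_sum,
)

__all__ = ["DurationAudit", "AuditResults"]

_CATEGORY_LABELS = {
    RelationshipCategory.EQUAL: "Calculated duration equal to written duration",
    RelationshipCategory.CALC_LESS: "Calculated duration less than written duration",
    RelationshipCategory.CALC_GREATER: "Calculated duration greater than written duration",
}


class DurationAudit:
    """Prescription-duration audit model.

    Parameters
    ----------
    data
        Extract rows in the input CSV schema (all columns may be text;
        empty string means absent).
    config
        Study window, intervention boundary, tolerance, exclusions.
    lexicon
        Frequency lexicon; defaults to the built-in table, or the CSV
        named by ``config.lexicon_path``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        config: Optional[AuditConfig] = None,
        lexicon: Optional[FrequencyLexicon] = None,
    ) -> None:
        self.config = config or AuditConfig()
        if lexicon is None:
            if self.config.lexicon_path:
                lexicon = FrequencyLexicon.from_csv(self.config.lexicon_path)
            else:
                lexicon = FrequencyLexicon.default()
        self.lexicon = lexicon
        self.data = data
        self._source: Optional[str] = None

    @classmethod
    def from_csv(cls, path, config: Optional[AuditConfig] = None, **kwargs) -> "DurationAudit":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        model = cls(df, config=config, **kwargs)
        model._source = str(path)
        return model

    @classmethod
    def from_records(
        cls, records: list[PrescriptionRecord], config: Optional[AuditConfig] = None, **kwargs
    ) -> "DurationAudit":
        from .records import records_to_dataframe

        return cls(records_to_dataframe(records), config=config, **kwargs)

    def fit(self) -> "AuditResults":
        cfg = self.config
        records, malformed = records_from_dataframe(self.data)
        log = NormalizationLog(malformed_rows=malformed)
        included, flow = apply_inclusion(records, cfg.excluded_drugs)
        normalized, log = normalize_records(included, self.lexicon, log)
        comparisons, flow = build_comparison_cohort(
            normalized, flow, tolerance=cfg.tolerance_days, round_calculated=cfg.round_calculated
        )
        pre, post, pooled, kept = split_periods(
            comparisons,
            cfg.intervention_datetime,
            flow,
            study_start=cfg.study_start,
            study_end=cfg.study_end,
        )

        # general documentation-quality measures over the full included
        # populations (not just the comparison cohort), per period
        period_rows = {"pre": [], "post": []}
        for norm in normalized:
            ts = norm.record.ordered_at
            if not (cfg.study_start <= ts < cfg.study_end):
                continue
            period_rows["pre" if ts < cfg.intervention_datetime else "post"].append(norm)

        estimates: dict[str, ProportionEstimate] = {}
        tests: dict[str, TestResult] = {}
        quality_counts: dict[str, dict[str, int]] = {}
        for period, rows in period_rows.items():
            n = len(rows)
            missing = sum(
                1
                for x in rows
                if x.record.written_duration_value is None
                or x.record.written_duration_unit is None
            )
            uncomputable = sum(
                1
                for x in rows
                if calculated_duration(
                    x.record.quantity,
                    x.record.strength_mg,
                    x.max_dose_mg,
                    x.administrations_per_day,
                )
                is None
            )
            ranged = sum(1 for x in rows if x.dose_was_range)
            quality_counts[period] = {
                "n": n,
                "missing_written": missing,
                "uncomputable": uncomputable,
                "ranged_dose": ranged,
            }
            if n > 0:
                for name, count in (
                    ("missing_written", missing),
                    ("uncomputable", uncomputable),
                    ("ranged_dose", ranged),
                ):
                    estimates[f"{period}_{name}"] = proportion_ci(
                        count, n, method=cfg.ci_method
                    )

        for period, counts in (("pre", pre), ("post", post), ("pooled", pooled)):
            if counts.n == 0:
                continue
            for cat in RelationshipCategory:
                estimates[f"{period}_{cat.value}"] = proportion_ci(
                    counts.count(cat), counts.n, method=cfg.ci_method
                )

        def add_two_prop(key: str, c1: int, m1: int, c2: int, m2: int) -> None:
            # a category absent (or universal) in both periods gives an
            # empty margin: no comparison is possible, the test is omitted
            if m1 > 0 and m2 > 0 and 0 < c1 + c2 < m1 + m2:
                tests[key] = two_proportion_test(c1, m1, c2, m2, correction=cfg.chi2_correction)

        if pre.n > 0 and post.n > 0:
            for cat in RelationshipCategory:
                add_two_prop(
                    f"{cat.value}_pre_post", pre.count(cat), pre.n, post.count(cat), post.n
                )
            omnibus = [
                [pre.equal, pre.calc_less, pre.calc_greater],
                [post.equal, post.calc_less, post.calc_greater],
            ]
            cols = [c for c in zip(*omnibus) if sum(c) > 0]
            if len(cols) >= 2:
                tests["omnibus_pre_post"] = chi_square_table(
                    list(zip(*cols)), correction=cfg.chi2_correction
                )
        npre, npost = quality_counts["pre"]["n"], quality_counts["post"]["n"]
        for name in ("missing_written", "uncomputable", "ranged_dose"):
            add_two_prop(
                f"{name}_pre_post",
                quality_counts["pre"][name], npre,
                quality_counts["post"][name], npost,
            )

        # monthly volumes over the full included population
        pre_months, pre_ppm = monthly_volumes(
            [n.record for n in period_rows["pre"]], cfg.study_start, cfg.intervention_datetime
        )
        post_months, post_ppm = monthly_volumes(
            [n.record for n in period_rows["post"]], cfg.intervention_datetime, cfg.study_end
        )
        if len(pre_months) >= 2 and len(post_months) >= 2:
            tests["monthly_volume_t"] = t_test_means(
                pre_months.to_numpy(), post_months.to_numpy(), welch=cfg.welch
            )
        if len(pre_ppm) > 0 and len(post_ppm) > 0:
            tests["per_patient_month_ranksum"] = wilcoxon_rank_sum(
                pre_ppm.to_numpy(), post_ppm.to_numpy()
            )

        comparison_df = pd.DataFrame(
            {
                "rx_id": [c.rx_id for c in kept],
                "period": [
                    "pre" if c.ordered_at < cfg.intervention_datetime else "post" for c in kept
                ],
                "ordered_at": [c.ordered_at.isoformat() for c in kept],
                "written_days": [c.written_duration_days for c in kept],
                "calculated_days": [c.calculated_duration_days for c in kept],
                "category": [c.category.value for c in kept],
                "unit_converted": [c.unit_converted for c in kept],
                "dose_was_range": [c.dose_was_range for c in kept],
            }
        )

        provenance = {
            "input": self._source or "<dataframe>",
            "software": f"rxaudit {_version}",
            "generated_at": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        }
        return AuditResults(
            flow=flow,
            pre=pre,
            post=post,
            pooled=pooled,
            estimates=estimates,
            tests=tests,
            quality_counts=quality_counts,
            monthly_counts={"pre": pre_months, "post": post_months},
            per_patient_month={"pre": pre_ppm, "post": post_ppm},
            comparisons=comparison_df,
            log=log,
            config_echo=cfg.echo(),
            provenance=provenance,
        )


@dataclass
class AuditResults:
    """Fitted audit: counts, estimates, tests, and report writers."""

    flow: CohortFlow
    pre: CategoryCounts
    post: CategoryCounts
    pooled: CategoryCounts
    estimates: dict[str, ProportionEstimate]
    tests: dict[str, TestResult]
    quality_counts: dict[str, dict[str, int]]
    monthly_counts: dict[str, pd.Series]
    per_patient_month: dict[str, pd.Series]
    comparisons: pd.DataFrame
    log: NormalizationLog
    config_echo: dict
    provenance: dict

    def summary(self) -> str:
        """Human-readable audit summary (counts, percentages, P values)."""
        lines = []
        lines.append("Written vs calculated opioid prescription duration audit")
        lines.append("=" * 58)
        f = self.flow
        lines.append(f"Total prescriptions in extract:        {f.n_total}")
        lines.append(f"  excluded non-oral/non-tablet:        {f.n_excluded_route_form}")
        lines.append(f"  excluded buprenorphine/methadone:    {f.n_excluded_drug}")
        lines.append(f"  no written duration documented:      {f.n_missing_written_duration}")
        lines.append(f"  written unit not convertible:        {f.n_excluded_nonconvertible_unit}")
        lines.append(f"  calculated duration uncomputable:    {f.n_uncomputable_calculated}")
        lines.append(f"  outside study window:                {f.n_excluded_out_of_window}")
        lines.append(f"Final comparison cohort:               {f.n_final}")
        lines.append(f"  written duration unit converted:     {f.n_unit_converted}")
        lines.append("")
        header = (
            f"{'Relationship':<48}"
            f"{'Pre (N=%d)' % self.pre.n:>18}"
            f"{'Post (N=%d)' % self.post.n:>18}"
            f"{'P value':>10}"
            f"{'Total (N=%d)' % self.pooled.n:>20}"
        )
        lines.append(header)
        for cat in (
            RelationshipCategory.EQUAL,
            RelationshipCategory.CALC_LESS,
            RelationshipCategory.CALC_GREATER,
        ):
            cells = []
            for period, counts in (("pre", self.pre), ("post", self.post)):
                if counts.n:
                    pct = round_half_up(100.0 * counts.count(cat) / counts.n)
                    cells.append(f"{counts.count(cat)} ({pct:.2f})")
                else:
                    cells.append("-")
            test = self.tests.get(f"{cat.value}_pre_post")
            p = _fmt_p(test.p_value) if test else "-"
            if self.pooled.n:
                pooled_pct = round_half_up(100.0 * self.pooled.count(cat) / self.pooled.n)
                pooled_cell = f"{self.pooled.count(cat)} ({pooled_pct:.2f})"
            else:
                pooled_cell = "-"
            lines.append(
                f"{_CATEGORY_LABELS[cat]:<48}{cells[0]:>18}{cells[1]:>18}{p:>10}{pooled_cell:>20}"
            )
        omnibus = self.tests.get("omnibus_pre_post")
        if omnibus:
            lines.append(
                f"Omnibus 3x2 chi-square: statistic={omnibus.statistic:.2f}, "
                f"df={omnibus.df:.0f}, P={_fmt_p(omnibus.p_value)}"
            )
        lines.append("")
        for name, label in (
            ("missing_written", "No written duration documented"),
            ("uncomputable", "Calculated duration uncomputable"),
            ("ranged_dose", "Ranged discrete dose"),
        ):
            pre_e = self.estimates.get(f"pre_{name}")
            post_e = self.estimates.get(f"post_{name}")
            test = self.tests.get(f"{name}_pre_post")
            if pre_e and post_e:
                lines.append(
                    f"{label}: {pre_e} vs {post_e}"
                    + (f", P={_fmt_p(test.p_value)}" if test else "")
                )
        vol = self.tests.get("monthly_volume_t")
        if vol:
            mpre, mpost = self.monthly_counts["pre"], self.monthly_counts["post"]
            lines.append(
                f"Monthly volume: mean {mpre.mean():.2f} (SD {mpre.std(ddof=1):.2f}) pre vs "
                f"{mpost.mean():.2f} (SD {mpost.std(ddof=1):.2f}) post, P={_fmt_p(vol.p_value)}"
            )
        ppm = self.tests.get("per_patient_month_ranksum")
        if ppm:
            spre, spost = self.per_patient_month["pre"], self.per_patient_month["post"]
            lines.append(
                "Prescriptions per patient-month: median "
                f"{spre.median():.0f} (IQR {spre.quantile(0.25):.0f}-{spre.quantile(0.75):.0f}) pre vs "
                f"{spost.median():.0f} (IQR {spost.quantile(0.25):.0f}-{spost.quantile(0.75):.0f}) post, "
                f"P={_fmt_p(ppm.p_value)}"
            )
        return "\n".join(lines)

    def summary_frame(self) -> pd.DataFrame:
        """The relationship table as a DataFrame (counts, percents, P)."""
        rows = []
        for cat in (
            RelationshipCategory.EQUAL,
            RelationshipCategory.CALC_LESS,
            RelationshipCategory.CALC_GREATER,
        ):
            test = self.tests.get(f"{cat.value}_pre_post")
            rows.append(
                {
                    "relationship": _CATEGORY_LABELS[cat],
                    "pre_n": self.pre.count(cat),
                    "pre_pct": round_half_up(100.0 * self.pre.count(cat) / self.pre.n)
                    if self.pre.n
                    else None,
                    "post_n": self.post.count(cat),
                    "post_pct": round_half_up(100.0 * self.post.count(cat) / self.post.n)
                    if self.post.n
                    else None,
                    "p_value": test.p_value if test else None,
                    "total_n": self.pooled.count(cat),
                    "total_pct": round_half_up(100.0 * self.pooled.count(cat) / self.pooled.n)
                    if self.pooled.n
                    else None,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        """Machine-readable report with full-precision numbers."""
        return {
            "flow": {k: getattr(self.flow, k) for k in vars(self.flow)},
            "counts": {
                period: {
                    "n": c.n,
                    "equal": c.equal,
                    "calc_greater": c.calc_greater,
                    "calc_less": c.calc_less,
                }
                for period, c in (("pre", self.pre), ("post", self.post), ("pooled", self.pooled))
            },
            "quality_counts": self.quality_counts,
            "estimates": {
                key: {
                    "count": e.count,
                    "n": e.n,
                    "percent": e.percent,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "ci_level": e.ci_level,
                }
                for key, e in self.estimates.items()
            },
            "tests": {
                key: {
                    "statistic": t.statistic,
                    "p_value": t.p_value,
                    "test_name": t.test_name,
                    "df": t.df,
                }
                for key, t in self.tests.items()
            },
            "config": self.config_echo,
            "provenance": self.provenance,
        }

    def to_files(self, output_dir) -> dict[str, Path]:
        """Write the report bundle; returns the paths written."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "comparisons": out / "comparisons.csv",
            "summary": out / "summary.csv",
            "flow": out / "cohort_flow.csv",
            "report": out / "report.json",
            "issues": out / "issues.log",
        }
        self.comparisons.to_csv(paths["comparisons"], index=False)
        self.summary_frame().to_csv(paths["summary"], index=False)
        self.flow.to_frame().to_csv(paths["flow"], index=False)
        paths["report"].write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        paths["issues"].write_text("\n".join(self.log.to_lines()) + "\n")
        return paths


def _fmt_p(p: float) -> str:
    if p < 0.001:
        return "<.001"
    if p < 0.0095:
        return f"{p:.3f}".lstrip("0")
    return f"{p:.2f}".lstrip("0")
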