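# Methods

## The audit model

A prescription's sig determines how fast its dispensed supply can be
consumed. With `Q` tablets dispensed, per-tablet strength `s` (mg),
maximum dose per administration `D` (mg) and `f` administrations per
24-hour day, the number of possible administrations is `Q·s / D` and the
**calculated duration** is

    T_calc = (Q·s / D) / f        [days]

`rxaudit` compares `T_calc` with the prescriber-documented **written
duration** `T_w` (converted to days) and classifies each prescription as
EQUAL (|T_calc − T_w| ≤ τ), CALC_GREATER (T_calc − T_w > τ) or CALC_LESS
(otherwise); the three categories partition all valid pairs. The audit
then contrasts category proportions between a pre-intervention and a
post-intervention period.

Two normalization conventions are deliberate and biased in the same
direction:

- **PRN at maximum frequency.** "Twice a day PRN" is treated as two
  administrations per day; "every other day" as 0.5. As-needed dosing is
  counted at the fastest allowed schedule.
- **Ranged doses at the top of the range.** "10–15 mg" resolves to a
  15 mg maximum dose per administration.

Both choices make `T_calc` the *shortest* duration consistent with the
sig, so CALC_GREATER — supply outlasting the documented duration, the
direction that contradicts acute-pain prescribing guidance — is, if
anything, underestimated. The model assumes patients could take the
maximum; it says nothing about what patients actually took, and no
adherence, rationing or pharmacy-fill behaviour is modelled.

## Parameters that matter

| Parameter | Units | Default | Why |
|---|---|---|---|
| `tolerance_days` (τ) | days | 1e-9 | Effectively exact equality on rational inputs; a fractional `T_calc` (2.5 d) never matches an integer `T_w`. Configurable for sensitivity analysis. |
| `round_calculated` | – | off | Optionally rounds `T_calc` half-up to whole days (floor 1) before classification, to probe how much of the discrepancy is sub-day granularity. |
| unit factors | days | week = 7, month = 30, hour = 1/24 | Written-duration unit conversion; "doses" divides by `f` and is unconvertible when `f` is unknown. Every converted record carries a flag and is counted, so the share of non-day documentation is reportable. |
| `intervention_datetime` | timestamp | 2018‑09‑01 | Period boundary; ordered strictly before = pre. Defaults describe an 11 + 11 month window (2017‑10‑01 to 2019‑08‑01). |
| `excluded_drugs` | – | buprenorphine, methadone | Case-insensitive substring match; these agents are predominantly used for opioid use disorder, not analgesia. |
| frequency lexicon | admin/day | ~28 labels | Editable table (CSV merged over built-ins). EHR vocabularies vary; unknown labels make a record uncomputable rather than being guessed. |

## Statistical layer

Proportions are reported on the percent scale with **Wald** 95%
intervals, p ± z·√(p(1−p)/n), clipped to [0, 100]; Wilson is available
behind a flag. Wald collapses to zero width at p ∈ {0, 1} — a documented
limitation accepted because the Wald form is what the audit's interval
estimates reproduce. Pre/post category comparisons use the Pearson
chi-square on the 2×2 table **without continuity correction** (the
statistic then equals the squared pooled two-proportion z-statistic;
Yates correction is available and immaterial at audit-scale counts). A
3×2 omnibus chi-square is emitted alongside the per-category tests since
either analysis is defensible. Monthly order volumes are compared with a
two-sample t test (Welch by default, pooled optional) and
per-patient-per-month counts — heavily tied small integers — with a
rank-sum test using the tie-corrected normal approximation; an exact
permutation-enumeration route exists for small samples and serves as the
reference in validation. Display rounding is half-up to 2 decimals; full
precision is retained in the machine-readable report.

## Inclusion cascade

Filters apply in a fixed order, so each record leaves exactly once and
the flow satisfies `n_total = n_final + Σ exclusions` (asserted at run
time): (1) non-oral route or non-tablet formulation; (2) excluded drug;
(3) no written duration documented; (4) written-duration unit not
convertible to days; (5) calculated duration uncomputable (unmapped
frequency, unparseable dose, missing quantity/strength); (6) outside the
study window. The order matters only for doubly-defective records and
follows the narrative order in which an analyst would clean the extract.
Missing-field handling is propagate-and-count: nothing is imputed,
malformed rows are reported, and unit-converted records are counted
separately because conversion is informational, not an exclusion.
Refills pass through every filter like any other order; they simply tend
to lack written durations.

## Synthetic extract generator

The generator emulates the statistical structure the audit assumes, not
clinical reality. Per calendar month it draws an order count
(truncated normal), assigns orders to patients with geometric(0.6)
orders per patient-month (median 1, IQR 1–2), samples drug/strength/
frequency/duration from catalogs, and **solves the dispense quantity
from a drawn target category** by inverting the duration formula:
`Q = T_w · (D/s) · f` exactly for EQUAL, scaled by U(1.1, 3) and rounded
up for CALC_GREATER, by U(0.3, 0.9) and rounded down (floor one tablet)
for CALC_LESS, with post-rounding re-verification. This closes the loop:
with corruption probabilities at zero, the pipeline must recover every
record's intended category exactly, and category proportions are
multinomial around the configured mix otherwise.

Defaults are pinned to a ~1/20 scale-down of a large two-hospital
outpatient service (≈214 orders/month pre, ≈206 post, 1,520 patients,
22 months) so the default pipeline runs in seconds;
`GeneratorConfig.study_scale()` restores full magnitudes (≈4,285/4,121
orders per month, ≈30,400 patients, ≈92,000 orders). Corruption defaults:
missing written durations 33.54% pre / 9.45% post, applied with a 5×
preference for refills (renewals carry forward a blank field that the
mandatory-entry intervention does not reach); uncomputable sigs 6.01% /
3.61%, applied with a 50× preference for records already missing their
written duration, since in practice both defects stem from the same
free-texted orders; ranged doses 4.5%; non-day duration units 3.6%.
Category mixes default to (38.86, 17.95, 43.19)% pre and (44.35, 16.21,
39.44)% post for (EQUAL, CALC_GREATER, CALC_LESS). Randomness is one
numpy Generator seeded once and consumed in a fixed documented order, so
a seed is reproducible and new options must fork substreams rather than
reshuffle existing draws.

What the generator does **not** emulate: realistic drug-name or
indication distributions, seasonal or secular prescribing trends (the
only temporal structure is the pre/post step), within-patient
correlation of sigs, or pharmacy fill behaviour. Passing tests therefore
demonstrate that the pipeline measures what it claims on data with the
assumed structure — not that any particular institution's extract has
that structure.

## Numerical choices and degenerate inputs

- Partial final administrations count fractionally: supply-exhaustion
  time is `Q / (tablets-per-administration · f)` days. The stepwise
  consumption oracle adopts the same convention and is required to agree
  with the algebraic formula to 1e-9 days; it exists purely as an
  independent verification path.
- Tablets per administration may be fractional (half-tablets); no
  rounding below the whole-day sensitivity switch.
- Dose parsing accepts `A mg` and `A-B mg` (hyphen or en dash, optional
  whitespace, decimals); inverted ranges and anything else are parse
  failures, never guesses — a silent misparse would corrupt the headline
  statistic.
- Degenerate statistics: empty chi-square margins omit the test from the
  report rather than erroring; an all-tied rank-sum input returns p = 1
  with a warning; identical constant series give t-test p = 1.
- Timestamps exactly at the intervention boundary are post-period
  (strict-before = pre).

## Problem sizes

Default validation runs use the 1/20-scale generator (~4,700 records).
The category-mix recovery check runs at full study scale (~72,000
auditable records across periods of ~31,300 and ~41,000), chosen as the
size at which 3-SE recovery bounds are a meaningful constraint; the
type-I calibration uses 1,000 replicate null comparisons at 500 per arm.

## Known limitations

- The Wald interval misbehaves near 0% and 100%; the audit's category
  proportions live comfortably inside (9%, 45%), where Wald and Wilson
  agree to the second decimal.
- Prescriptions are treated as independent observations; within-patient
  correlation is not modelled (noted, not corrected).
- The frequency lexicon is a lookup table, not a natural-language sig
  parser; free-text frequencies outside it are counted uncomputable.
- Duration-unit factors (month = 30 d) are conventions, configurable but
  arbitrary at the margins.
- No multiple-testing adjustment is applied across the reported tests.
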