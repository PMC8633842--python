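# Methods

## Setting and data model

The pipeline targets month-granular Japanese employer-insurance claims:
subscriber records carry sex and year-month of birth; enrollment is a set
of covered calendar months; diagnoses, procedures and dispensed drugs are
filed per claim month, with day-level dates available only on some fields.
Mothers and infants enrolled with the same insurer are linkable, but the
infant's day of birth is withheld (re-identification protection), so the
birth is known only to the month. Codes are treated as opaque strings with
category labels; no ICD-10 or national reimbursement dictionary is
interpreted.

Dates are explicit `(year, month, optional day)` triples
(`PartialDate`); all arithmetic is day-granular and restricted to full
dates, which prevents silently mixing month-level and day-level precision.
Files are comma-separated UTF-8 with ISO-8601 dates. Reading is fail-soft:
rows violating a type invariant (e.g. `days_supply = 0`, gestational age
outside 0–44 weeks, a date outside the study window) are rejected
individually with line-level diagnostics and the load proceeds — claims
feeds are dirty, and an audit trail beats silent repair. The gestational-age
ceiling of 44 weeks exceeds the 42-week post-term threshold with margin.

## Episode dating

**Delivery.** Among delivery-related entries day-dated within the infant's
birth month, the preferred tier (selected delivery diagnoses and surgical
procedures) is consulted first and its earliest date taken; only when that
tier is empty is the earliest date among any other delivery-related entry
(other diagnoses, medical procedures, injectable medications) used — strict
tier precedence, so a selected entry beats an *earlier* other-tier entry.
Entries dated outside the birth month are ignored; month-only entry dates
cannot anchor a day and are likewise unusable. With no usable entry the
15th of the birth month is assigned (normal deliveries are often not
insurance-covered and leave no trace), bounding the delivery error by the
half-month, ≤16 days. All entry codes sharing the chosen earliest date are
recorded for auditability.

**Onset.** Among day-dated diagnoses carrying a gestational age in
completed weeks, the maximal GA wins; ties go to the *latest* diagnosis
date, because GA recorded nearer delivery reflects the best obstetric
estimate. Onset is the diagnosis date minus `7·GA` days — completed weeks
with zero extra days — so when the GA-bearing visit records the completed
weeks of the true gestational age, the raw onset overshoots truth by the
truncation remainder only, 0–6 days. Month-only GA diagnoses are excluded
(the subtraction is day-granular). A mother with no usable GA diagnosis, or
whose implied onset does not precede the estimated delivery (a degenerate
combination the source rules never address), is *undatable* and exits at
eligibility criterion 3.

**Post-term cap.** Estimated gestations exceeding 294 days (42 weeks, the
threshold at which induction is recommended) are uniformly reset: onset
becomes `delivery − 294` days, delivery staying anchored, and the episode
is flagged. The pre-cap (raw) onset is retained on the episode so the
subtraction rule and the cap rule can be evaluated separately.

## Cohort selection

Four criteria applied in order, with counts after each step (an attrition
flowchart): (1) the linked infant's first enrollment month equals its birth
month; (2) the mother is enrolled in each of the 11 calendar months
preceding the birth month; (3) the episode is datable; (4) the mother is
enrolled in every calendar month intersecting
`[onset − 180 d, delivery + 180 d]`. Enrollment over an interval is
evaluated at calendar-month granularity — the database's native unit — so
a window partially covering a month requires that month. Final membership
is a conjunction and hence order-independent; the report fixes the order
above. A mother with several linked infants contributes her earliest birth
only; the extra links are dropped and counted.

## Exposure classification and tabulation

Kampo products are selected by ATC prefix (default `V03AX`). Each record's
event date is the dispensing date, else the hospitalization date, else the
15th of the claim month, with the choice recorded as provenance; the
exposure interval runs `days_supply` days from the event date inclusive.
The three windows — pre-pregnancy `[onset−180, onset−1]`, pregnancy
`[onset, delivery]` (both endpoints pregnant days), postpartum
`[delivery+1, delivery+180]` — are pairwise disjoint and tile the exposure
span exactly (361 + gestation days). An interval is assigned to *every*
window it intersects, since days of supply estimate the duration of
exposure and a supply spanning a boundary exposes both windows; a
start-date-only convention is available as `window_assignment="start"` for
sensitivity analysis. Counting deduplicates per person–formula–window: a
formula counts once per person per window and once in the any-window total,
however often it was dispensed; formulas dispensed simultaneously each
count. Crude decoction drugs flow through identical logic under their own
category and reporting threshold.

Percentages are `100·n/denominator` rounded half-up to one decimal
(`decimal.Decimal`, not float rounding); the reporting thresholds — 0.4%
for extract formulas, 0.1% for crude drugs — apply to the *rounded* total
percentage, which reproduces boundary rows whose raw frequency is just
above or below the printed threshold. Sorting is by total count descending,
formula name ascending on ties; filtering is idempotent. Maternal age at
delivery uses the 15th of the mother's birth month as birthdate proxy and a
365.25-day year; dispersion is the sample SD (a single-member cohort
reports SD 0). The cautionary-ingredient map records, per formula, only the
constituents relevant to pregnancy caution (rhubarb, peach kernel, moutan
bark, safflower, achyranthes root, anhydrous sodium sulfate, processed
aconite root); a formula missing from the map is flagged "unknown
ingredients" rather than silently passing, and the map is user-editable
via YAML.

## Synthetic claims generator

The generator emulates the observation process, not any disease process.
Per mother: gestation ~ Normal(270.1, 13.5) days truncated to [150, 310];
age at delivery ~ Normal(32.3, 4.5) years truncated to [18, 45]; delivery
date uniform over 2008-01 to 2015-06 (clear of the 2005–2016 study-window
edges). Antenatal visits run 4-weekly from week 8 and 2-weekly from week
24 — a standard Japanese schedule; each visit emits a diagnosis whose GA
equals the completed weeks of true gestational age at the visit, and a
delivery-day GA diagnosis appears with probability 0.9. Delivery entries
are drawn independently per tier with p(selected) = 0.371 and
p(other) = 0.235, chosen so the unconditional delivery-method mix is
37.1% selected / 14.8% other-only / 48.1% fallback, matching observed
claims practice. Formula dispensing is Bernoulli per (formula, window) with
catalog probabilities anchored to observed distinct-person prevalences
(e.g. shoseiryuto 0.015 / 0.107 / 0.041 across pre/pregnancy/post); supply
intervals are placed uniformly *within* the true window so the ground-truth
window labels are exact and prevalence estimates unbiased. Days of supply
are drawn from {5, 7, 14, 21, 28}.

A configurable fraction (default 0.15) of mothers is made ineligible by one
targeted defect — infant enrolled a month late, a missing month among the
11 pre-birth months, a missing month inside the exposure span, or removal
of all GA-bearing diagnoses — so generator eligibility labels and pipeline
selection can be compared exactly. Missingness is a separate, composable
layer (`degrade_dates`): dispensing dates survive with probability 0.864,
convert to hospitalization dates with 0.014, and otherwise vanish (claim
month always survives, forcing the mid-month path); delivery entries can be
removed for a chosen fraction of mothers. Randomness uses one seed with
per-mother substreams derived from `(seed, mother index)`, so output is
byte-reproducible and invariant to generation order.

What the generator does **not** emulate: twins and multiple pregnancies per
mother, pregnancy losses (abortion/stillbirth pregnancies are outside the
design), insurer switching, seasonality or autocorrelation in dispensing,
GA mis-recording, and drug–outcome associations. Passing recovery tests
therefore demonstrates correctness of the reconstruction rules under the
stated observation model, not robustness to every failure mode of real
claims.

## Verification strategy and problem sizes

Three layers, all run in the default test suite: (i) arithmetic
identities — every cell of the embedded published benchmark tables
(33 extract formulas, 22 crude drugs, denominator 33,941) is reproduced
through the tabulation code path; (ii) analytic rule checks — the 294-day
cap (a raw onset 300 days before delivery yields exactly 294 and the
capped flag), the 15th-day fallbacks, the week-39 subtraction (273 days),
and window tiling; (iii) recovery on a seeded 2,000-mother simulation with
delivery-week GA diagnoses and full dates — delivery recovered exactly for
all episodes, raw onset within 6 days of truth for 100% (the completed-week
truncation bound; capped episodes additionally equal `delivery − 294`
exactly), delivery error ≤30 days with all delivery entries removed,
window assignment equal to a brute-force per-day membership scan on 10,000
random intervals, and per-window prevalence within 3 binomial SEs of each
generating probability. For catalog cells whose expected count is tiny
(n·p < ~1) the normal 3-SE band is degenerate, so those cells are judged by
the exact binomial tail at the same 3-sigma significance level. Property
tests (hypothesis, derandomized) cover date round-trips, the longest-GA
estimator against an exhaustive scan, monotonicity under added smaller-GA
diagnoses, the per-day window oracle, and union bounds on deduplicated
counts. Simulation sizes (300 mothers for default-condition tests, 2,000
for recovery, 600 × high-probability catalog for provenance calibration)
keep the whole suite under ~10 s while leaving binomial checks
well-powered.
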