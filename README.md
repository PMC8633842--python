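# kampo-claims

Drug-utilization analysis of traditional Japanese (Kampo) medicine
prescriptions around pregnancy, reconstructed from month-granular
administrative health-insurance claims.

Japanese claims databases record diagnoses, procedures, and dispensed drugs
per calendar month, link mothers to infants enrolled with the same insurer
(infant birth is known only to the month), and never record pregnancy onset
or delivery dates directly. This package implements the standard
claims-based reconstruction used in Japanese pharmacoepidemiology and the
downstream prescription-frequency tabulation, for analysts who need a
tested, reusable pipeline — together with a synthetic claims generator with
known ground truth, since real claims extracts are proprietary.

## The algorithm

For each mother linked to an infant born in month *B*:

- **Delivery date** — the earliest day-dated delivery-related entry within
  *B*, consulting preferred delivery diagnoses/surgical procedures
  (tier *selected*) first and any other delivery-related entry (tier
  *other*) only if none exist; with no usable entry, the 15th of *B*
  (uninsured normal deliveries leave no claims trace).
- **Onset date** — among diagnoses carrying a gestational age (GA, completed
  weeks), take the one with maximal GA (later date on ties) and set
  `onset = diagnosis_date − 7·GA` days. A "delivery at week 39" diagnosis
  subtracts exactly 273 days.
- **Post-term cap** — if `delivery − onset > 294` days (42 weeks),
  `onset := delivery − 294` and the episode is flagged capped.
- **Eligibility** — (1) infant first enrolled in its birth month; (2) mother
  enrolled the 11 calendar months before *B*; (3) pregnancy datable;
  (4) mother enrolled every month intersecting
  `[onset − 180 d, delivery + 180 d]`.
- **Exposure** — drug records under ATC prefix V03AX become supply
  intervals `[event_date, event_date + days_supply − 1]` (event date:
  dispensing > hospitalization > 15th of claim month) and are assigned to
  every window they intersect among pre-pregnancy `[onset−180, onset−1]`,
  pregnancy `[onset, delivery]`, postpartum `[delivery+1, delivery+180]`.
  A formula counts once per person per window; percentages are
  `100·n/denominator` rounded half-up to one decimal, reported at ≥0.4%
  (extract formulas) or ≥0.1% (crude decoction drugs).

## Worked example

```python
from kampo_claims import (SimParams, StudyConfig, simulate_bundle,
                          estimate_episodes, select_cohort)

params = SimParams(n_mothers=500, seed=7)
bundle, truth = simulate_bundle(params)
config = StudyConfig()
episodes = estimate_episodes(bundle, config)
cohort, attrition = select_cohort(bundle, episodes, config)
for label, n in attrition.steps:
    print(f"{n:>4}  {label}")
```

prints the selection flowchart

```
 500  linked mother-infant pairs
 488  infant enrolled from birth month
 473  enrolled 11 months before birth
 456  pregnancy datable
 437  enrolled across the full exposure span
```

i.e. of 500 simulated linked mothers, 437 satisfy all four criteria — and
the selected set equals the generator's eligibility labels exactly.
Continuing through exposure classification and tabulation
(`examples/04_frequency_tables.py`) yields, over the 437-mother denominator:

```
 formula_name  total_n  total_pct  pre_pct  pregnancy_pct  post_pct
     kakkonto       68       15.6      2.1            7.8       6.6
  shoseiryuto       60       13.7      1.1            9.6       4.1
```

kakkonto was dispensed to 68 distinct cohort members (15.6%), 7.8% of the
cohort during pregnancy — each person counted once per window however many
dispensings occurred. The same run reports mean age at delivery 32.2 (SD
4.7) years and mean gestation 267.4 (SD 14.1) days, with 2.5% of episodes
post-term capped.

The `examples/` scripts walk one capability each (simulation, dating,
cohort/exposure, reporting); a thin CLI offers the same stages as shell
subcommands (`kampo-claims simulate|estimate|cohort|classify|tabulate`).

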