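# Methods

This note documents the models, rules and design choices behind
`sofa2audit`: what is computed, under which assumptions, and which
defaults are editable conventions rather than facts.

## 1. First-day SOFA-2 scoring

The engine reduces event streams to per-stay worst values over the window
`[intime, intime + 24 h]` (closed at both ends) and maps them through
configured threshold bands:

| component      | worst value                         | direction |
|----------------|-------------------------------------|-----------|
| neurological   | min GCS total (motor as fallback)   | lower     |
| cardiovascular | min MAP                             | lower     |
| respiratory    | min PaO₂/FiO₂ (S/F fallback)        | lower     |
| hepatic        | max bilirubin (mg/dL)               | higher    |
| renal          | max creatinine; total urine (mL/24h)| higher; lower |
| coagulation    | min platelets (×10³/µL)             | lower     |

Rule logic, in evaluation order per component:

* **Respiratory.** P/F governs whenever at least one ratio can be formed;
  S/F is used only otherwise, and only SpO₂ readings strictly below 98%
  enter the ratio (per-reading exclusion; a mixed stream keeps its sub-98
  readings). FiO₂ is carried forward (LOCF) to each PaO₂/SpO₂ time,
  capped at 4 h staleness; FiO₂ = 0 pairings are skipped with an audit
  note. Bands scoring 3–4 require an in-window advanced ventilatory
  episode (IMV, NIV, CPAP, BiPAP, HFNC or ECMO); without one the band is
  capped at 2. Both streams absent ⇒ component missing.
* **Cardiovascular.** Any in-window MCS episode forces the maximum (4).
  Otherwise, qualifying vasopressor exposure — a configured agent whose
  merged infusion episode overlaps the window by ≥60 min; episodes of the
  same drug separated by <15 min are merged, and durations are never
  summed across distinct drugs — selects agent-count tier rules
  (1 agent → 2, 2 → 3, ≥3 → 4 by default; the event schema carries no
  dose, so tiers are keyed on agent count). With no qualifying pressor,
  graduated MAP bands apply. No MAP, drugs or devices ⇒ missing.
* **Neurological.** Worst GCS total; if absent, the worst motor score via
  its own band table. Any in-window infusion of a configured delirium
  agent (dexmedetomidine, haloperidol, quetiapine, ziprasidone,
  olanzapine) floors the result at 1 — after the motor fallback and even
  when no GCS was charted at all, since the floor is unconditional.
* **Renal.** In-window RRT forces 4; otherwise the worse of the
  creatinine band and the 24-h urine-output band (total mL over the
  window; weight normalisation is not applied because weight is often
  unavailable). Both streams absent without RRT ⇒ missing.
* **Hepatic / coagulation.** Single-analyte band lookups.
* **Missing components score 0** (presumed normal); the flag is cleared
  when a treatment rule (delirium floor, vasopressors, RRT, MCS)
  supplies information despite absent measurements. The respiratory
  component is an exception by construction: with no oxygenation data it
  is missing even on support.

Every nonzero subscore records the rule label that produced it
(`*_rule` columns), so scores are auditable row by row.

**Thresholds are data.** Each band in `sofa2_default.yaml` declares its
own lower/upper edge and inclusivity; there is no global open/closed
convention. The shipped cut-points are the maintainers' transcription of
the SOFA-2 structure (revised oxygenation bands with the S/F fallback and
support gating, graduated MAP bands, vasopressor tiers, RRT/MCS maxima,
revised bilirubin/platelet bands); sites holding an authoritative
threshold table should override the file — the engine treats it purely as
configuration, and the test suite pins its own fixture bands rather than
the shipped numbers.

## 2. Cohort construction

* One index stay per patient: adults (age ≥ 18), the first
  hospitalization containing an ICU visit, and within it the
  earliest-`intime` ICU stay. Hospitalizations are ordered by hospital
  admission time by default; `order_by="intime"` switches to ICU in-time
  ordering for data without admission times.
* Exclusions, in fixed order (attrition counts are order-dependent):
  ICU length of stay < 6 h (strict: exactly 6 h is retained), then any
  worst value outside its plausibility range. The shipped ranges
  (`plausibility_default.yaml`) are deliberately permissive artifact
  defaults, not a published supplement.
* Outcome: death at or before `outtime + 6 h` (grace window
  configurable; the boundary itself counts as an ICU death).
* The attrition log records, per step, counts, an age/sex/race/language/
  insurance summary, and standardized mean differences against the
  initial population, `SMD = |m_a − m_b| / sqrt((sd_a² + sd_b²)/2)` with
  `sd = sqrt(p(1−p))` for proportions; SMD ≤ 0.10 is annotated as
  minimal imbalance. A zero pooled SD with unequal means yields NaN
  (undefined) rather than a fabricated number.
* Timestamps are timezone-naive and treated as a single clock, matching
  deidentified, date-shifted data.

## 3. Subgroup mapping

Five dimensions: age bands `[18,45) [45,65) [65,75) [75,∞)` (left-closed,
labels `18-44 … 75+`), sex, race/ethnicity (White/Black/Hispanic/Asian/
Other/Unknown), language (English/Non-English/Unknown) and insurance
(Private/Medicare/Medicaid/Other). Raw labels are matched
case-insensitively against editable vocabularies; "unknown", "unable to
obtain" and "patient declined" map to Unknown, and small groups (Native
Hawaiian/Pacific Islander, American Indian/Alaska Native, multiple races)
fold into Other. Any raw label containing "HISPANIC" takes precedence
over a recorded race (configurable, `hispanic_precedence`). Unmapped
labels fall to a per-dimension default and are counted, never dropped;
Unknown is analysed as its own category, not imputed.

## 4. Performance evaluation

* **AUROC** uses the Mann–Whitney rank form with ties counted ½, which
  equals trapezoidal ROC integration; the test suite checks both the
  identity against an independent trapezoid implementation and a
  brute-force pairwise-concordance oracle to 1e-12.
* **CIs**: percentile bootstrap (default, 1,000 resamples) for internal
  consistency with the ΔAUROC procedure; an analytic DeLong interval is
  available (`ci_method="delong"`).
* **Calibration** follows the offset convention: slope from the free
  logistic refit `logit y = α + b·L`, intercept from `logit y = α` with
  `L` as fixed offset, Wald 95% CIs. Evaluated on the fitting cohort
  itself these return (0, 1) to optimizer tolerance — an algebraic
  consequence of the MLE score equations, used as a correctness check.
  A joint-fit intercept would differ; the offset form is the primary
  definition here.
* **ΔAUROC** resamples stays with replacement *within* each comparison
  group (stratified; an unstratified pooled option exists), recomputes
  both AUROCs per iteration, and takes the 2.5/97.5 percentiles of the
  differences; the point estimate is the plug-in difference. Replicates
  that lose an outcome class are redrawn up to 10× the iteration budget,
  then the interval is flagged unstable rather than silently biased.
  Significance ⇔ the CI excludes 0; |ΔAUROC| > 0.05 is additionally
  flagged as potentially clinically meaningful.
* Degenerate subgroups (single outcome class) are reported with NaN
  metrics and an explanatory flag, never dropped from the table.
* Calibration curves smooth observed outcomes against predicted risk
  with lowess (span configurable).

## 5. Synthetic cohort generator

The generator is an artifact model of an ICU validation cohort, not a
physiologic simulator. Defaults emulate the marginal structure of a large
single-centre adult ICU population: demographic marginals and age-band
weights follow a published baseline table (56.1% male, 66.1% White,
14.3% unknown race, 52.8% Medicare, …); the component missingness
defaults use the published hepatic (58%) and cardiovascular (0%) rates,
with the remaining four set as plausible artifact values; length of stay
is lognormal with median ≈1.9 days.

Mechanics: a latent severity `s ~ Beta(mean 0.23, concentration 5)` is
jittered per organ and linearly interpolated between a healthy and a
maximally deranged anchor value per analyte (plus noise), so all bands
are exercised at every severity level; treatment episodes (ventilation,
vasopressors, RRT, MCS, delirium agents) are drawn with probabilities
rising in the relevant derangement, including sub-60-minute infusions
that must *not* qualify. The *true score* is obtained by running the
scoring engine on the full emitted streams — generator and engine cannot
disagree by construction. Mortality is then

```
logit P(death) = α₀ + β·true_score + shift(subgroups) + ε,
ε ~ N(0, sd(subgroups)²)
```

with defaults α₀ = −4.1, β = 0.24 chosen so the default cohort
reproduces the target marginals (≈7% ICU mortality, true-score AUROC
≈0.77, true-score median 3 with IQR 2–7). `subgroup_intercept_shifts`
("dimension:category" keys) inject mis-calibration; `subgroup_noise_sd`
injects score-independent risk that dilutes discrimination without
touching the integer score — both default to zero (a null cohort).
Deaths are placed inside the stay (85%) or in the 6 h grace window, and
3% of survivors die after the window, so both outcome branches occur.
Component streams are then dropped at the missingness rates (treatments
are never dropped, mirroring how orders outlive charting). Each table
draws from its own seeded stream, so output is reproducible and adding a
table never perturbs the others.

**What passing tests do and do not show.** The generator has no
inter-organ correlation beyond shared severity, no time-series dynamics,
no real label noise in demographics, and its outcome model is exactly the
logistic form the audit assumes. Tests therefore demonstrate that the
pipeline recovers structure that is truly present — not that SOFA-2 is
fair or well calibrated on any real population.

## 6. Numerical choices and problem sizes

* Logistic fits use IRLS (statsmodels GLM, tol 1e-10); non-convergence or
  |coefficient| > 1000 (separation) raises a fit error.
* Quantiles use linear interpolation (type 7); LOS is reported in days to
  one decimal.
* Tests run at deliberately modest sizes chosen for statistical
  resolution: marginal recovery and shift recovery at n = 20,000 (3 SE /
  Monte-Carlo bands), discrimination-dilution trends at n = 8,000 per
  noise level, the null behaviour of the significance flag at 500
  replicates of two n = 1,000 groups with 200 bootstrap iterations, and
  oracle equivalence on 200 random instances with n ≤ 500.
* Single-seed confidence-interval *coverage* assertions are avoided
  (a 95% CI misses 5% of the time by design); tests assert point
  recovery within Monte-Carlo error and interval-width consistency, plus
  a dedicated DeLong coverage simulation across 500 replicates.

## 7. Known limitations

* The shipped threshold table is a structural transcription, not an
  official SOFA-2 supplement; deployments must review it.
* Vasopressor tiers ignore dose (not present in the event schema) and
  norepinephrine-equivalent conversion is out of scope.
* Original 1996 SOFA scoring, serial daily scores, pre-sedation GCS
  adjustment, hospital (vs ICU) mortality and multiple-testing
  adjustment across subgroup comparisons are deliberately not
  implemented.
* Whether the renal "biochemical initiation" criterion should use
  analytes beyond creatinine is left to configuration (disabled by
  default: the default table expresses RRT and band rules only).
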