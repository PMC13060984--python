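# sofa2audit

Tools for computing **first-day SOFA-2 organ-dysfunction scores** from
event-level ICU records and for auditing how well the score predicts ICU
mortality **across demographic subgroups** — by age band, sex,
race/ethnicity, primary language and insurance — the way an external
validation / fairness study of a severity score is run on a database such
as MIMIC-IV.

It is aimed at clinical-informatics and biostatistics researchers who have
ICU data in a simple relational shape (stays, timestamped measurements,
infusion intervals, organ-support episodes) and want a reproducible,
configurable pipeline rather than one-off scripts. Because the real data
of interest are credentialed, the package ships a seeded synthetic cohort
generator that emulates the statistical structure of such a cohort, so
every stage is testable end to end without any download.

## What it computes

**Score.** SOFA-2 assigns each of six organ systems — neurological (GCS),
cardiovascular (MAP and vasopressors), respiratory (PaO₂/FiO₂ with an
SpO₂/FiO₂ fallback and support-gated top bands), hepatic (bilirubin),
renal (creatinine, urine output, RRT) and coagulation (platelets) — a
subscore of 0–4 from the *worst* value in the first 24 h of the ICU stay;
the total is 0–24. Missing components score 0 (presumed normal).
Treatment rules are applied as data: RRT and mechanical circulatory
support force the maximal renal/cardiovascular subscore, qualifying
vasopressor exposure (≥60 min) selects agent-count tiers, and
pharmacologic delirium treatment floors the neurologic subscore at 1.
Every numeric cut-point lives in an editable YAML rule set.

**Audit.** With ICU mortality `y` (death in the ICU or within 6 h of
discharge) and first-day score `s`:

* discrimination: AUROC in the Mann–Whitney form
  `P(s_death > s_survivor) + ½·P(tie)`, with percentile-bootstrap or
  DeLong 95% CIs;
* calibration: fit `logit p = a + b·s` on the overall cohort, keep the
  linear predictor `L = â + b̂·s`, and per subgroup estimate the
  calibration slope (coefficient of `L` in a free logistic refit) and the
  calibration intercept (free constant with `L` as fixed offset); (0, 1)
  is perfect calibration;
* subgroup gaps: ΔAUROC versus a reference category with a stratified
  nonparametric bootstrap (1,000 iterations), significant when the 95%
  percentile CI excludes 0 and flagged clinically meaningful when
  |ΔAUROC| > 0.05;
* observed mortality at each score level (0–14, ≥15 pooled) per subgroup,
  a baseline-characteristics table, an attrition log with standardized
  mean differences, and a per-component missingness report.

## Worked example

```bash
sofa2audit simulate --n 5000 --seed 11 --out demo/data
sofa2audit report --data demo/data --out demo/out --seed 11
```

or in Python:

```python
import sofa2audit as sa

cohort = sa.generate_cohort(sa.GeneratorConfig(n_stays=5000, seed=11))
sa.write_cohort(cohort, "demo/data")
sa.run_pipeline("demo/data", "demo/out",
                eval_config=sa.EvalConfig(n_boot=1000, seed=11))
```

`demo/out/performance.csv` then contains (abridged, rounded):

```
dimension category    n  deaths  auroc  delta_auroc  cal_intercept  cal_slope  significant
  overall  Overall 4969     357  0.765          NaN         -0.000      1.000        False
age_group    18-44  646      48  0.769          NaN          0.085      1.082        False
age_group    45-64 1568     114  0.776        0.007         -0.009      1.064        False
age_group    65-74 1141      80  0.767       -0.003         -0.043      0.966        False
age_group      75+ 1614     115  0.750       -0.020          0.005      0.933        False
      sex     Male 2779     181  0.754          NaN         -0.074      0.968        False
      sex   Female 2190     176  0.775        0.021          0.084      1.026        False
```

Reading it: the overall cohort (n = 4,969 after exclusions, observed
mortality 7.2%) shows AUROC 0.765; the overall calibration intercept and
slope are exactly (0, 1) because the calibration model is fitted to the
same cohort it is evaluated on — the subgroup rows are where departures
carry information. Reference categories (`18-44`, `Male`, …) carry no
ΔAUROC. This default cohort injects no subgroup effects, so no gap is
significant; passing `subgroup_intercept_shifts={"sex:Female": 0.5}` to
`GeneratorConfig` would reappear as a ≈+0.5 shift in the Female
calibration intercept.

The run also writes `baseline_table.csv` (e.g. overall: median score 3
(IQR 1–5), median LOS 2.0 days (1.1–3.5)), `mortality_by_score.csv`,
`attrition.json`, `missingness.json`, calibration-curve data, two PNG
figures, and a `manifest.json` with input/output digests for
reproducibility.

## Configuration files

* `sofa2_config.yaml` — the entire SOFA-2 rule set (threshold bands with
  explicit edge inclusivity, drug lists, window and duration constants).
  The shipped default is an editable transcription; see
  `docs/methods.md`.
* `plausibility.yaml` — admissible worst-value ranges used by the
  exclusion cascade (permissive artifact defaults).
* `subgroups.yaml` — raw-label vocabularies, age-band edges and reference
  levels for the five audit dimensions.
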