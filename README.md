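# diabrisk

External validation of non-invasive type-2-diabetes (T2D) risk scores.

In resource-limited settings, blood-based diagnostic testing (fasting plasma
glucose, HbA1c) cannot be applied population-wide. A two-step screening
strategy instead uses a questionnaire-style risk score built from
non-invasive predictors — age, waist circumference, BMI, blood pressure,
family history, physical activity — to decide who should receive a blood
test. Before such a score is used in a new population it must be externally
validated: how well does it separate people with prevalent undiagnosed T2D
from those without (**discrimination**), and do its predicted probabilities
match observed frequencies (**calibration**)?

`diabrisk` is a reusable pipeline for exactly this task. It ships a
declarative engine for four published score families (ADRS, Simplified
FINDRISC, ADA, IRS — coefficients are configuration files, not code), dual
glycaemic case definitions (FPG ≥ 7 mmol/L, HbA1c ≥ 6.5 %), and a seeded
synthetic cohort generator emulating a three-visit African cohort study, so
the entire methodology is testable without access to any restricted data.

## Statistics implemented

* **Discrimination** — C-statistic
  `c = P(p_case > p_noncase) + ½·P(tie)` with the nonparametric DeLong
  structural-components standard error and 95 % CI; ROC curves; optimal
  thresholds by the Youden index `J = se + sp − 1` and the top-left distance
  `√((1−se)² + (1−sp)²)`; independent-samples z-test for C between disjoint
  subgroups (sex, median age, BMI 25 kg/m², rural/urban).
* **Calibration** — E/O ratio `ΣP_i / ΣY_i` with Poisson 95 % CIs
  (`E/O · exp(±1.96/√O)`, exact limits optional); Brier score; Yates
  (discrimination) slope; Hosmer–Lemeshow chi-square on risk deciles;
  binned calibration-curve tables.
* **Recalibration** — intercept update: every probability is shifted on the
  log-odds scale by `Δ = ln[odds(prevalence)/odds(mean predicted)]`,
  one-step (default) or iterated to the exact fixed point. Being monotone,
  recalibration never changes discrimination.

The scorer (`RiskScore`) and recalibrator (`InterceptRecalibrator`) follow
the scikit-learn estimator API (`fit`/`predict_proba`, `fit`/`transform`)
and compose with sklearn pipelines; the statistics are plain functions.

## Worked example

```bash
diabrisk simulate --seed 42 --out cohort.csv
diabrisk validate --cohort cohort.csv --out report/
```

The first command writes 2 811 visit rows (937 participants × 3 visits).
The second assembles the analysis dataset per criterion, filters each model
to its complete cases, scores, recalibrates and writes `report/report.json`
plus flattened CSVs. The cells table begins:

```
model                criterion state         n  cases eo_ratio brier  c    optimal_threshold sens  spec
ADRS                 FPG       original      797 111   0.23    0.13   0.77 0.03              76.6  66.2
ADRS                 FPG       recalibrated  797 111   0.95    0.11   -    0.13              76.6  66.2
ADA                  FPG       original      432  66   4.72    0.45   0.69 0.89              51.5  78.1
ADA                  FPG       recalibrated  432  66   1.41    0.13   -    0.35              51.5  78.1
```

Reading it: the ADRS discriminates acceptably (C = 0.77) but, with its link
anchored to a lower-prevalence source population, predicts only 0.23 of the
observed case count (E/O = 0.23, underestimation); a single intercept
update brings E/O to 0.95. The ADA score overestimates almost five-fold and
remains miscalibrated even after recalibration — the same qualitative
pattern on both the FPG and HbA1c case definitions. Cells with fewer than
100 events carry a precision warning (here ADA and IRS, whose family-history
requirement costs ~40 % of participants to missingness).

Library use mirrors the CLI:

```python
from diabrisk import (SimConfig, generate_cohort, assemble_analysis_dataset,
                      FPG_CRITERION, complete_case_filter, bundled_spec,
                      score_cohort, c_statistic, eo_ratio)

visits, true_model = generate_cohort(SimConfig(), seed=42)
cohort = complete_case_filter(
    assemble_analysis_dataset(visits, FPG_CRITERION), bundled_spec("adrs"))
scored = score_cohort(bundled_spec("adrs"), cohort)
p, y = scored["probability"].to_numpy(), scored["case"].to_numpy(float)
print(c_statistic(p[y == 1], p[y == 0]).c, eo_ratio(p, y).ratio)
```

Score specifications are JSON/YAML documents validated against
`src/diabrisk/schemas/score_spec.schema.json`; the bundled transcriptions
are provisional (see each file's `citation`) and user-supplied specs are
first-class.

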