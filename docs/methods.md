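# Methods

## Study design being modelled

The pipeline targets cross-sectional external validation of non-invasive
risk scores for *prevalent undiagnosed* type-2 diabetes in a longitudinal
cohort with up to three visits. A participant is a case if fasting plasma
glucose (FPG) ≥ 7 mmol/L **or** HbA1c ≥ 6.5 % at any visit, with the two
analytes analysed as separate case definitions throughout. Case records are
taken at the first visit at which the active criterion is met; noncase
records at baseline. Participants on glucose-lowering medication at any
visit are excluded (their glycaemia no longer reflects undiagnosed
disease), as are participants whose active analyte was never measured
(indeterminate — never silently treated as noncase). A participant with the
analyte missing at some visits counts as a noncase only if below threshold
at *every* visit where it was measured; this conservative rule is a design
choice, since visit-level missingness has no canonical treatment in this
design. No imputation is performed anywhere: exclusion for missing data is
model-specific (each score is validated on its own complete-case cohort),
which mirrors how differential missingness — family history in particular —
shrinks the sample differently per score.

Hypertensive status has two operational definitions, and each score spec
declares which it consumes: a composite (self-report, or BP medication, or
measured BP ≥ 140/90 mmHg) used by scores that include clinic blood
pressure, and BP-medication-only for the FINDRISC family, which asks about
treatment rather than measurement.

## Score engine

A score is data, not code: an ordered list of items mapping predictors to
points (interval or category lookups) or linear coefficients, plus a
probability link. Interval items are lower-inclusive half-open `[lo, hi)`,
matching the ≥ convention of the diagnostic thresholds; waist items may
carry sex-specific cut points. Points scores convert to probabilities via a
two-parameter logistic link `p = expit(a + b·s)` stored in the spec (point
systems do not natively emit probabilities; anchoring the link in the spec
file keeps the engine model-agnostic). Logistic-form scores use their
linear predictor directly. A missing required predictor raises a
not-applicable signal — a default value is never substituted. The four
bundled specs are provisional transcriptions from the scores' primary
publications; the ADRS itself is unpublished, so its coefficients (and all
link parameters) are synthetic stand-ins chosen once to reproduce the
qualitative behaviour reported for these scores — under-estimation for
ADRS/FINDRISC/IRS, gross over-estimation for the ADA score, whose source
population has a far higher baseline prevalence. Coefficients are never
refit; recalibration touches the intercept only.

## Discrimination

The C-statistic is computed by midranks, which is algebraically the
pair-count definition (ties count ½) and is asserted against an exhaustive
pairwise oracle in the tests. "Nonparametric methods" is implemented as the
DeLong structural-components variance; subgroup contrasts use an
independent-samples z-test, appropriate because the strata are disjoint
(paired DeLong would be needed only for two scores on the same subjects,
which is not the reported comparison). Classification is positive iff
probability ≥ threshold. The ROC polyline has one point per distinct
predicted value plus the all-negative endpoint, so its trapezoidal area
equals the C-statistic identically; Youden and top-left optima are taken
over observed thresholds with ties resolved to the lowest threshold. The
main report pairs sensitivity/specificity with the Youden threshold and
reports the top-left threshold alongside.

## Calibration and recalibration

E/O uses sums of predicted probabilities over observed case counts; its CI
treats O as Poisson with the log-normal approximation
`E/O · exp(±1.96/√O)` (exact Poisson limits behind a flag — the
approximation is the conventional choice and the two agree closely for
O ≥ 25). Brier score follows the standard convention (0 = perfect;
literature occasionally inverts the verbal description, but reported values
are only consistent with the standard definition). Hosmer–Lemeshow uses
ten quantile bins (merged on tied boundaries, error below three usable
bins) with `χ² = Σ (O_b − E_b)²/(E_b(1 − p̄_b))` and **df = number of
bins**: the probabilities under validation are fully pre-specified, so no
degrees of freedom are lost to estimation; `g − 2` applies to development
data where the model was fit to the same sample, and would inflate the
type-I error here to ~11 %. The Monte-Carlo acceptance test confirms the
nominal rate under df = g.

One-step intercept recalibration applies
`Δ = ln[odds(prev)/odds(p̄)]` on the log-odds scale. For heterogeneous
probabilities one step does not make E/O exactly 1; the `iterated` mode
repeats compute-then-apply until `|Σp′ − Σy| < 10⁻⁶·n` (≤ 100 iterations),
and both modes are labelled in output. Recalibration is computed per model
× criterion on that model's complete-case cohort, so each uses its own
prevalence. Subgroup statistics are computed on recalibrated probabilities
by default (with flags for original probabilities and for per-stratum
refactoring; the default applies the overall correction factor to strata).
Since the intercept shift is strictly monotone, the C-statistic is
provably unchanged by recalibration — asserted to 1e-12 in every report
cell. Strata with fewer than 10 cases, and cohorts below the conventional
100-events/100-nonevents precision rule, carry warnings rather than errors.

## Synthetic cohort

The generator is first-class, tested code. Defaults: 937 participants,
70 % women, truncated-normal age (mean 52, SD 10, minimum 30 years),
log-normal BMI (median 25 kg/m²), waist regressed on BMI and sex (slope
2.3 cm per kg/m², residual SD 6 cm), measured blood pressure with 60 %
awareness and partial treatment of hypertension, 20 % family-history
prevalence with 40 % missingness, three physical-activity grades, 56 %
rural dwellers. FPG case status follows a single logistic "true model" on
age (0.08/yr), waist (0.06/cm), composite hypertension (0.70) and male sex
(−0.30); the HbA1c case latent shares the same linear predictor shifted by
+0.889 log-odds, coupled to the FPG latent through a Gaussian copula
(ρ = 0.7), so the two case sets overlap strongly but disagree realistically
and the HbA1c prevalence (~26 %) exceeds the FPG prevalence (~14 %).
Analyte values are class-conditional truncated normals around the
diagnostic thresholds. Intercept (−11.811), HbA1c shift and a small
eligibility offset (−0.036, reflecting that medication exclusion removes
severe cases only) were calibrated once by large-sample Monte Carlo so that
the *assembled* analysis cohort hits the target prevalences and the
reported true model is calibrated for the population actually analysed;
these constants are frozen defaults, not tuning knobs.

Diagnosis timing is spread over visits (80/12/8 % of cases first cross the
threshold at visits 1/2/3), exercising the first-diagnosis selection rule
without altering who is a case. Extra noncase→case conversion ("incidence
per visit") exists for longitudinal experiments but defaults to zero:
conversions are drawn outside the true model, so any nonzero default would
make the generating model structurally miscalibrated against its own
cohort and void the recovery guarantees. 10 % of severe cases (FPG ≥ 9
mmol/L or HbA1c ≥ 8 %) receive glucose-lowering medication and are thereby
excluded downstream. All missingness is MCAR (per participant for
questionnaire covariates, per visit for analytes); covariates are held
constant across a participant's visits.

What passing tests therefore do and do not show: the generator reproduces
the *marginal* structure and the case-definition mechanics of a real
screening cohort, so pipeline correctness, recovery and operating
characteristics transfer; it does not model covariate drift between
visits, informative missingness, assay error, or covariate correlations
beyond those induced by the regression structure, so empirical performance
numbers for the bundled scores on synthetic data are illustrative, not
estimates for any real population. The implied population AUC of the true
model (~0.77 by 200 000-sample Monte Carlo) was chosen to sit in the range
typical of non-invasive diabetes scores.

## Numerical choices and problem sizes

The C-statistic is computed as a single division of an exactly
representable midrank sum, making it bit-identical to the pair-count
oracle. CIs are truncated to [0,1]; degenerate groups of size one get zero
variance contribution. Threshold ties break to the lowest candidate;
quantile bins merge on tied boundaries; age-median and BMI-25 splits send
ties to the upper stratum. Monte-Carlo checks use 200 replicates of
n = 1000 (Hosmer–Lemeshow type-I error), 500 replicates of n = 200 (DeLong
coverage), 100 replicates of n = 2000 (miscalibration direction), and a
single n = 10 000 cohort for recovery — sizes at which the targeted bands
(nominal ±4 %, coverage 92–98 %, |Δ| < 0.05) are comfortably resolved
while the whole suite runs in well under a minute. Reports round C and E/O
to 2 decimals and sensitivity/specificity to 1 in CSV; JSON retains full
precision and round-trips losslessly.

## Known limitations

* Bundled score coefficients and links are provisional transcriptions;
  validating the real published scores requires replacing the spec files
  with verified transcriptions (the engine and schema support this without
  code changes).
* No OGTT case definition; no multiple imputation; no calibration-slope
  refitting; no figure rendering (ROC and calibration-bin tables export to
  CSV for any plotting tool).
* The independent-samples subgroup z-test assumes large-ish strata; cells
  with < 10 cases are flagged rather than suppressed.
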