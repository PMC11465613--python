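"""Synthetic longitudinal cohort generator.

Emulates the structure of a three-visit South African cohort study of
screen-detected type-2 diabetes: ~70% women, ages truncated-normal above 30
(mean 52), log-normal BMI (median 25 kg/m2), waist circumference regressed on
BMI and sex, measured blood pressure with partially aware/treated
hypertension, 56% rural dwellers, heavy missingness in family history
(~40%), and two correlated glycaemic analytes (FPG, HbA1c) whose diagnostic
thresholds (7 mmol/L, 6.5%) yield discordant case sets — roughly 14%
prevalence by FPG and 26% by HbA1c at the defaults.

Case status by FPG is governed by a single logistic "true model" on age,
waist circumference, hypertensive status and sex; the HbA1c case latent
shares the same linear predictor shifted by a constant on the log-odds
scale, with a Gaussian copula (rho = 0.7 by default) coupling the two
analytes.  The true model's intercept (and the HbA1c shift) are calibrated
by large-sample Monte Carlo so that the *assembled* analysis cohort —
after first-diagnosis visit selection and medication exclusion — hits the
target prevalences; the resulting constants are frozen in the defaults.

Diagnosis timing is spread over the three visits (80/12/8% of cases first
cross the threshold at visits 1/2/3), which exercises the first-diagnosis
selection rule without decoupling assembled prevalence from the true model.
Additional noncase-to-case conversion ("incidence") is available but
defaults to zero, since such conversions are outside the true model and
would break its calibration by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit

from .cohort import VISIT_COLUMNS, hypertension_composite
from .scores import ProbabilityLink, ScoreItem, ScoreSpec

__all__ = [
    "SimConfig",
    "TrueModel",
    "generate_cohort",
    "inject_missingness",
    "make_longitudinal",
    "implied_auc",
]

#: frozen Monte-Carlo-calibrated constants (see module docstring)
_CALIBRATED_INTERCEPT = -11.811
_CALIBRATED_HBA1C_SHIFT = 0.889
#: log-odds offset aligning the reported true model with the analysis
#: population: medication exclusion removes (severe) cases only, so the
#: screening-eligible population sits slightly below the raw generating model
_CALIBRATED_ELIGIBILITY_OFFSET = -0.036


def _default_missingness() -> dict[str, float]:
    return {
        "waist_circumference": 0.08,
        "bmi": 0.05,
        "bp_medication": 0.03,
        "hypertension": 0.05,
        "family_history_dm": 0.40,
        "physical_activity": 0.10,
        "fpg": 0.03,
        "hba1c": 0.05,
    }


@dataclass
class SimConfig:
    """Generative parameters of the synthetic cohort (defaults = study conditions)."""

    n_participants: int = 937
    seed: int = 0
    female_fraction: float = 0.70
    # age: truncated normal, years
    age_mean: float = 52.0
    age_sd: float = 10.0
    age_min: float = 30.0
    # BMI: log-normal, kg/m2
    bmi_median: float = 25.0
    bmi_log_sd: float = 0.18
    # waist | bmi, sex: linear regression, cm
    wc_intercept_female: float = 28.0
    wc_intercept_male: float = 34.0
    wc_slope: float = 2.3
    wc_resid_sd: float = 6.0
    # blood pressure, mmHg
    sbp_mean: float = 128.0
    sbp_sd: float = 17.0
    dbp_intercept: float = 18.0
    dbp_slope: float = 0.5
    dbp_resid_sd: float = 8.0
    htn_awareness: float = 0.60       # P(self-report yes | measured hypertensive)
    htn_false_report: float = 0.05    # P(self-report yes | not measured hypertensive)
    bp_med_rate_aware: float = 0.50   # P(BP medication | self-report yes)
    bp_med_rate_other: float = 0.02
    family_history_prev: float = 0.20
    activity_probs: tuple = (0.35, 0.40, 0.25)  # ordinal categories 1 (low) .. 3
    rural_fraction: float = 0.56
    # true logistic model for FPG-defined prevalent undiagnosed T2D
    true_intercept: float = _CALIBRATED_INTERCEPT
    beta_age: float = 0.08
    beta_wc: float = 0.06
    beta_htn: float = 0.70
    beta_male: float = -0.30
    hba1c_shift: float = _CALIBRATED_HBA1C_SHIFT  # log-odds shift of the HbA1c latent
    eligibility_offset: float = _CALIBRATED_ELIGIBILITY_OFFSET
    rho: float = 0.70                 # copula correlation between the two analytes
    # class-conditional analyte distributions (truncated normal)
    fpg_case_mean: float = 8.3
    fpg_case_sd: float = 1.2
    fpg_noncase_mean: float = 5.3
    fpg_noncase_sd: float = 0.7
    fpg_floor: float = 3.5
    fpg_ceiling: float = 15.0
    hba1c_case_mean: float = 7.4
    hba1c_case_sd: float = 1.0
    hba1c_noncase_mean: float = 5.6
    hba1c_noncase_sd: float = 0.45
    hba1c_floor: float = 4.0
    hba1c_ceiling: float = 14.0
    # visit structure
    visit_count: int = 3
    dx_visit_probs: tuple = (0.80, 0.12, 0.08)  # first-diagnosis visit among cases
    incidence_per_visit: float = 0.0            # extra noncase->case conversion
    medication_rate: float = 0.10               # P(glucose-lowering meds | severe case)
    severe_fpg: float = 9.0
    severe_hba1c: float = 8.0
    missingness: dict = field(default_factory=_default_missingness)

    def validate(self) -> None:
        probs = [
            self.female_fraction, self.htn_awareness, self.htn_false_report,
            self.bp_med_rate_aware, self.bp_med_rate_other,
            self.family_history_prev, self.rural_fraction,
            self.incidence_per_visit, self.medication_rate,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probability parameters must lie in [0, 1]")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if abs(sum(self.activity_probs) - 1.0) > 1e-9:
            raise ValueError("activity_probs must sum to 1")
        if abs(sum(self.dx_visit_probs) - 1.0) > 1e-9:
            raise ValueError("dx_visit_probs must sum to 1")
        if len(self.dx_visit_probs) != self.visit_count:
            raise ValueError("dx_visit_probs must have one entry per visit")
        if any(not 0.0 <= r <= 1.0 for r in self.missingness.values()):
            raise ValueError("missingness rates must lie in [0, 1]")
        # diagnostic thresholds must fall inside the latent analyte support
        if not self.fpg_floor < 7.0 < self.fpg_ceiling:
            raise ValueError("FPG threshold outside latent support: infeasible prevalence")
        if not self.hba1c_floor < 6.5 < self.hba1c_ceiling:
            raise ValueError("HbA1c threshold outside latent support: infeasible prevalence")

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["activity_probs"] = list(self.activity_probs)
        payload["dx_visit_probs"] = list(self.dx_visit_probs)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if "activity_probs" in payload:
            payload["activity_probs"] = tuple(payload["activity_probs"])
        if "dx_visit_probs" in payload:
            payload["dx_visit_probs"] = tuple(payload["dx_visit_probs"])
        return cls(**payload)


@dataclass(frozen=True)
class TrueModel:
    """The generating logistic model for FPG-defined case status."""

    intercept: float
    beta_age: float
    beta_wc: float
    beta_htn: float
    beta_male: float

    def linear_predictor(self, records: pd.DataFrame) -> np.ndarray:
        htn = records["hypertension_composite"].eq("yes").to_numpy(dtype=float)
        male = records["sex"].eq("male").to_numpy(dtype=float)
        return (
            self.intercept
            + self.beta_age * records["age"].to_numpy(dtype=float)
            + self.beta_wc * records["waist_circumference"].to_numpy(dtype=float)
            + self.beta_htn * htn
            + self.beta_male * male
        )

    def predicted_probability(self, records: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(records))

    def to_score_spec(self, intercept_shift: float = 0.0, name: str = "TRUE_MODEL") -> ScoreSpec:
        """Express the generating model as a logistic-form score spec."""
        return ScoreSpec(
            name=name,
            form="logistic",
            intercept=self.intercept + intercept_shift,
            items=[
                ScoreItem(predictor="age", kind="linear_coefficient",
                          coefficient=self.beta_age),
                ScoreItem(predictor="waist_circumference", kind="linear_coefficient",
                          coefficient=self.beta_wc),
                ScoreItem(predictor="hypertension_composite", kind="categorical_points",
                          values={"yes": self.beta_htn, "no": 0.0}),
                ScoreItem(predictor="sex", kind="categorical_points",
                          values={"male": self.beta_male, "female": 0.0}),
            ],
            probability_link=ProbabilityLink(kind="direct_logistic"),
            description="synthetic generating model (ground truth for recovery tests)",
        )


def _true_model(config: SimConfig, reported: bool = False) -> TrueModel:
    """Generating model; ``reported=True`` applies the eligibility offset.

    The raw model governs the case draws; the reported model (returned to the
    caller as ground truth) is calibrated for the medication-excluded
    analysis population.
    """
    offset = config.eligibility_offset if reported else 0.0
    return TrueModel(
        intercept=config.true_intercept + offset,
        beta_age=config.beta_age,
        beta_wc=config.beta_wc,
        beta_htn=config.beta_htn,
        beta_male=config.beta_male,
    )


def _draw_covariates(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One row per participant: baseline covariates, complete (no missingness)."""
    n = config.n_participants
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    a = (config.age_min - config.age_mean) / config.age_sd
    age = stats.truncnorm.ppf(
        rng.random(n), a, np.inf, loc=config.age_mean, scale=config.age_sd
    )
    bmi = np.exp(np.log(config.bmi_median) + config.bmi_log_sd * rng.standard_normal(n))
    wc_intercept = np.where(
        sex == "female", config.wc_intercept_female, config.wc_intercept_male
    )
    wc = wc_intercept + config.wc_slope * bmi + config.wc_resid_sd * rng.standard_normal(n)
    sbp = config.sbp_mean + config.sbp_sd * rng.standard_normal(n)
    dbp = (
        config.dbp_intercept
        + config.dbp_slope * sbp
        + config.dbp_resid_sd * rng.standard_normal(n)
    )
    measured_htn = (sbp >= 140) | (dbp >= 90)
    aware = np.where(measured_htn, config.htn_awareness, config.htn_false_report)
    sr_htn = np.where(rng.random(n) < aware, "yes", "no")
    med_p = np.where(sr_htn == "yes", config.bp_med_rate_aware, config.bp_med_rate_other)
    bp_med = np.where(rng.random(n) < med_p, "yes", "no")
    fam = np.where(rng.random(n) < config.family_history_prev, "yes", "no")
    activity = rng.choice([1.0, 2.0, 3.0], size=n, p=list(config.activity_probs))
    residency = np.where(rng.random(n) < config.rural_fraction, "rural", "urban")

    df = pd.DataFrame(
        {
            "participant_id": [f"P{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "waist_circumference": wc,
            "bmi": bmi,
            "systolic_bp": sbp,
            "diastolic_bp": dbp,
            "bp_medication": bp_med,
            "hypertension": sr_htn,
            "family_history_dm": fam,
            "physical_activity": activity,
            "residency": residency,
        }
    )
    df["hypertension_composite"] = hypertension_composite(df)
    return df


def _trunc_draw(rng, n, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.ppf(rng.random(n), a, b, loc=mean, scale=sd)


def _analyte_values(config, rng, active_case: np.ndarray, analyte: str) -> np.ndarray:
    """Per-visit analyte draw given the active diagnostic class of each participant."""
    n = len(active_case)
    if analyte == "fpg":
        case_args = (config.fpg_case_mean, config.fpg_case_sd, 7.0, config.fpg_ceiling)
        non_args = (config.fpg_noncase_mean, config.fpg_noncase_sd, config.fpg_floor, 7.0)
    else:
        case_args = (config.hba1c_case_mean, config.hba1c_case_sd, 6.5, config.hba1c_ceiling)
        non_args = (config.hba1c_noncase_mean, config.hba1c_noncase_sd, config.hba1c_floor, 6.5)
    out = np.empty(n, dtype=float)
    out[active_case] = _trunc_draw(rng, int(active_case.sum()), *case_args)
    out[~active_case] = _trunc_draw(rng, int((~active_case).sum()), *non_args)
    return out


def generate_cohort(
    config: SimConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, TrueModel]:
    """Generate the full visit table (n_participants x visit_count rows).

    Deterministic given the seed (``seed`` argument overrides
    ``config.seed``).  Returns the table in the cohort CSV dialect plus the
    generating :class:`TrueModel`.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_participants
    if n < 1:
        raise ValueError("n_participants must be positive")

    cov = _draw_covariates(config, rng)
    model = _true_model(config)
    lp = model.linear_predictor(cov)
    p_fpg = expit(lp)
    q_hba1c = expit(lp + config.hba1c_shift)

    # Gaussian copula couples the two case latents
    z1 = rng.standard_normal(n)
    z2 = config.rho * z1 + np.sqrt(1.0 - config.rho**2) * rng.standard_normal(n)
    case_fpg = stats.norm.cdf(z1) < p_fpg
    case_hba1c = stats.norm.cdf(z2) < q_hba1c

    any_case = case_fpg | case_hba1c
    dx_visit = np.ones(n, dtype=int)
    n_cases = int(any_case.sum())
    if n_cases:
        dx_visit[any_case] = rng.choice(
            np.arange(1, config.visit_count + 1),
            size=n_cases,
            p=list(config.dx_visit_probs),
        )

    # optional extra conversions beyond the true model (default rate 0)
    if config.incidence_per_visit > 0:
        at_risk = ~any_case
        for v in range(2, config.visit_count + 1):
            convert = at_risk & (rng.random(n) < config.incidence_per_visit)
            case_fpg |= convert
            case_hba1c |= convert
            dx_visit[convert] = v
            any_case |= convert
            at_risk &= ~convert

    visit_frames = []
    fpg_at_dx = np.full(n, np.nan)
    hba1c_at_dx = np.full(n, np.nan)
    for v in range(1, config.visit_count + 1):
        active_fpg = case_fpg & (v >= dx_visit)
        active_hba1c = case_hba1c & (v >= dx_visit)
        fpg_v = _analyte_values(config, rng, active_fpg, "fpg")
        hba1c_v = _analyte_values(config, rng, active_hba1c, "hba1c")
        at_dx = any_case & (dx_visit == v)
        fpg_at_dx[at_dx] = fpg_v[at_dx]
        hba1c_at_dx[at_dx] = hba1c_v[at_dx]
        frame = cov.drop(columns=["hypertension_composite"]).copy()
        frame["visit_index"] = v
        frame["fpg"] = fpg_v
        frame["hba1c"] = hba1c_v
        visit_frames.append(frame)

    severe = any_case & (
        (fpg_at_dx >= config.severe_fpg) | (hba1c_at_dx >= config.severe_hba1c)
    )
    on_med = severe & (rng.random(n) < config.medication_rate)

    # per-participant covariate missingness (baseline questionnaire, MCAR)
    cov_missing = {
        col: rng.random(n) < rate
        for col, rate in config.missingness.items()
        if col not in ("fpg", "hba1c") and col in cov.columns
    }

    rows = []
    for frame in visit_frames:
        frame = frame.copy()
        for col, mask in cov_missing.items():
            frame.loc[mask, col] = np.nan
        v = frame["visit_index"].iloc[0]
        frame["diabetes_medication"] = np.where(on_med & (v >= dx_visit), "yes", "no")
        # per-visit analyte missingness (MCAR)
        for col in ("fpg", "hba1c"):
            rate = config.missingness.get(col, 0.0)
            if rate > 0:
                frame.loc[rng.random(n) < rate, col] = np.nan
        rows.append(frame)

    visits = pd.concat(rows, ignore_index=True)
    visits = visits.sort_values(
        ["participant_id", "visit_index"], kind="mergesort"
    ).reset_index(drop=True)
    return visits[VISIT_COLUMNS], _true_model(config, reported=True)


def inject_missingness(table: pd.DataFrame, rates: dict[str, float], seed: int) -> pd.DataFrame:
    """Missing-completely-at-random masking per column; input left untouched."""
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for {col!r} outside [0, 1]")
        if col not in table.columns:
            raise ValueError(f"unknown column {col!r}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col, rate in rates.items():
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
    return out


def make_longitudinal(
    base: pd.DataFrame,
    incidence_per_visit: float = 0.05,
    medication_rate: float = 0.0,
    seed: int = 0,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Extend a single-visit table to three visits with incident conversion.

    Noncases (both analytes below threshold at visit 1) convert to cases at
    visits 2/3 with the given per-visit probability — glycaemia is redrawn
    above both thresholds from the case-class distributions.  A fraction of
    cases receives glucose-lowering medication (flagged from the diagnosis
    visit onward), exercising the exclusion rule downstream.
    """
    if not 0.0 <= incidence_per_visit <= 1.0:
        raise ValueError("incidence must lie in [0, 1]")
    if not 0.0 <= medication_rate <= 1.0:
        raise ValueError("medication rate must lie in [0, 1]")
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    base = base[base["visit_index"].eq(1)].reset_index(drop=True)
    n = len(base)
    if n == 0:
        raise ValueError("base cohort has no visit-1 rows")

    fpg = pd.to_numeric(base["fpg"], errors="coerce").to_numpy()
    hba1c = pd.to_numeric(base["hba1c"], errors="coerce").to_numpy()
    case_fpg = fpg >= 7.0
    case_hba1c = hba1c >= 6.5
    case_now = case_fpg | case_hba1c
    measured = ~np.isnan(fpg) | ~np.isnan(hba1c)
    dx_visit = np.where(case_now, 1, 0)

    frames = [base.copy()]
    at_risk = measured & ~case_now
    for v in (2, 3):
        convert = at_risk & (rng.random(n) < incidence_per_visit)
        dx_visit[convert] = v
        case_fpg |= convert  # converters cross both thresholds
        case_hba1c |= convert
        at_risk &= ~convert
        frame = base.copy()
        frame["visit_index"] = v
        new_fpg = _analyte_values(config, rng, case_fpg, "fpg")
        new_hba1c = _analyte_values(config, rng, case_hba1c, "hba1c")
        new_fpg[np.isnan(fpg) & ~case_fpg] = np.nan
        new_hba1c[np.isnan(hba1c) & ~case_hba1c] = np.nan
        frame["fpg"] = new_fpg
        frame["hba1c"] = new_hba1c
        frames.append(frame)

    on_med = (dx_visit > 0) & (rng.random(n) < medication_rate)
    out = []
    for frame in frames:
        v = frame["visit_index"].iloc[0]
        frame = frame.copy()
        frame["diabetes_medication"] = np.where(
            on_med & (v >= np.maximum(dx_visit, 1)), "yes",
            frame["diabetes_medication"],
        )
        out.append(frame)
    table = pd.concat(out, ignore_index=True)
    return (
        table.sort_values(["participant_id", "visit_index"], kind="mergesort")
        .reset_index(drop=True)[VISIT_COLUMNS]
    )


def implied_auc(config: SimConfig | None = None, n: int = 200_000, seed: int = 12345) -> float:
    """Large-sample Monte-Carlo AUC implied by the true model (FPG criterion)."""
    from .discrimination import c_statistic

    config = dataclasses.replace(config or SimConfig(), n_participants=n)
    rng = np.random.default_rng(seed)
    cov = _draw_covariates(config, rng)
    p = _true_model(config).predicted_probability(cov)
    labels = rng.random(n) < p
    if labels.all() or not labels.any():
        raise ValueError("degenerate prevalence in implied-AUC simulation")
    return c_statistic(p[labels], p[~labels]).c
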