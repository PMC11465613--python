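"""Cohort assembly for cross-sectional validation of diabetes risk scores.

The analysis dataset is built from a longitudinal visit table (up to three
visits per participant).  Prevalent undiagnosed type-2 diabetes is screen
detected by a glycaemic threshold — fasting plasma glucose (FPG) >= 7 mmol/L
or glycated haemoglobin (HbA1c) >= 6.5% — and a participant's record is taken
at the first visit at which the active criterion is met (cases) or at
baseline (noncases).  Participants on glucose-lowering medication at any
visit are excluded, as are participants for whom the active analyte was never
measured.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Visit-table columns, in canonical order.
VISIT_COLUMNS = [
    "participant_id",
    "visit_index",
    "age",
    "sex",
    "waist_circumference",
    "bmi",
    "systolic_bp",
    "diastolic_bp",
    "bp_medication",
    "hypertension",
    "family_history_dm",
    "physical_activity",
    "residency",
    "diabetes_medication",
    "fpg",
    "hba1c",
]

NUMERIC_COLUMNS = [
    "age",
    "waist_circumference",
    "bmi",
    "systolic_bp",
    "diastolic_bp",
    "physical_activity",
    "fpg",
    "hba1c",
]

CATEGORICAL_COLUMNS = [
    "sex",
    "bp_medication",
    "hypertension",
    "family_history_dm",
    "residency",
    "diabetes_medication",
]


@dataclass(frozen=True)
class DiagnosticCriterion:
    """A glycaemic case definition: analyte and inclusive threshold."""

    name: str           # "FPG" or "HBA1C"
    analyte: str        # visit-table column holding the analyte
    threshold: float    # mmol/L for FPG, percent for HbA1c
    inclusive: bool = True


FPG_CRITERION = DiagnosticCriterion("FPG", "fpg", 7.0)
HBA1C_CRITERION = DiagnosticCriterion("HBA1C", "hba1c", 6.5)

_CRITERIA = {"FPG": FPG_CRITERION, "HBA1C": HBA1C_CRITERION}


def get_criterion(name: str) -> DiagnosticCriterion:
    try:
        return _CRITERIA[name.upper()]
    except KeyError:
        raise ValueError(f"unknown diagnostic criterion {name!r}; expected FPG or HBA1C")


def classify_t2d(visit, criterion: DiagnosticCriterion) -> str:
    """Classify one visit as ``case``/``noncase``/``indeterminate``.

    ``indeterminate`` is returned when the criterion's analyte is missing;
    a missing analyte is never silently treated as a noncase.
    """
    value = visit[criterion.analyte]
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "indeterminate"
    return "case" if value >= criterion.threshold else "noncase"


def hypertension_composite(df: pd.DataFrame) -> pd.Series:
    """Composite hypertensive status: self-report, BP medication or measured BP.

    ``yes`` if any of self-reported hypertension, BP medication, systolic
    >= 140 mmHg or diastolic >= 90 mmHg; ``NaN`` when no component is a known
    yes and at least one component is missing; ``no`` otherwise.
    """
    sr_yes = df["hypertension"].eq("yes")
    med_yes = df["bp_medication"].eq("yes")
    sbp = pd.to_numeric(df["systolic_bp"], errors="coerce")
    dbp = pd.to_numeric(df["diastolic_bp"], errors="coerce")
    measured = sbp.ge(140) | dbp.ge(90)
    any_yes = sr_yes | med_yes | measured

    sr_known = df["hypertension"].isin(["yes", "no"])
    med_known = df["bp_medication"].isin(["yes", "no"])
    all_known = sr_known & med_known & sbp.notna() & dbp.notna()

    out = pd.Series(np.nan, index=df.index, dtype=object)
    out[any_yes] = "yes"
    out[~any_yes & all_known] = "no"
    return out


@dataclass
class AnalysisCohort:
    """Assembled analysis dataset under one diagnostic criterion.

    ``records`` holds one row per participant (index-visit predictors, a
    boolean ``case`` column and subgroup labels).  ``exclusions`` is the audit
    trail of ``(participant_id, reason)`` pairs.
    """

    criterion: DiagnosticCriterion
    records: pd.DataFrame
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.records)

    @property
    def n_cases(self) -> int:
        return int(self.records["case"].sum())

    @property
    def n_noncases(self) -> int:
        return self.n_total - self.n_cases

    @property
    def prevalence(self) -> float:
        return self.n_cases / self.n_total if self.n_total else float("nan")

    def with_records(self, records: pd.DataFrame, extra_warnings=()) -> "AnalysisCohort":
        return AnalysisCohort(
            criterion=self.criterion,
            records=records,
            exclusions=list(self.exclusions),
            warnings=list(self.warnings) + list(extra_warnings),
        )


def _add_subgroup_labels(records: pd.DataFrame) -> pd.DataFrame:
    """Attach sex / age-median / BMI-25 / residency subgroup labels.

    The age split uses the per-cohort median with ties assigned to the upper
    group; the BMI split is fixed at 25 kg/m2, ties upper.
    """
    records = records.copy()
    age_median = records["age"].median()
    records["age_group"] = np.where(
        records["age"].ge(age_median), ">=median", "<median"
    )
    records.loc[records["age"].isna(), "age_group"] = np.nan
    records["age_median_value"] = age_median
    records["bmi_group"] = np.where(records["bmi"].ge(25.0), ">=25", "<25")
    records.loc[records["bmi"].isna(), "bmi_group"] = np.nan
    return records


def assemble_analysis_dataset(
    visits: pd.DataFrame, criterion: DiagnosticCriterion
) -> AnalysisCohort:
    """Build the one-row-per-participant analysis dataset.

    Cases contribute the earliest visit at which the criterion is met;
    noncases (below threshold at every visit where the analyte is present)
    contribute their baseline (visit 1) record.  Exclusions: glucose-lowering
    medication at any visit; analyte missing at every visit; noncase without
    a baseline record.
    """
    if visits is None or len(visits) == 0:
        raise ValueError("empty visit table")
    missing_cols = [c for c in VISIT_COLUMNS if c not in visits.columns]
    if missing_cols:
        raise ValueError(f"visit table missing columns: {missing_cols}")

    visits = visits.sort_values(["participant_id", "visit_index"], kind="mergesort")
    exclusions: list[tuple[str, str]] = []
    warnings: list[str] = []

    on_med = visits.loc[
        visits["diabetes_medication"].eq("yes"), "participant_id"
    ].unique()
    exclusions.extend((pid, "diabetes_medication") for pid in on_med)
    visits = visits[~visits["participant_id"].isin(set(on_med))]

    analyte = pd.to_numeric(visits[criterion.analyte], errors="coerce")
    is_case_visit = analyte.notna() & analyte.ge(criterion.threshold)
    has_measure = (
        analyte.notna().groupby(visits["participant_id"]).any()
    )
    indeterminate_ids = has_measure.index[~has_measure]
    exclusions.extend((pid, "analyte_never_measured") for pid in indeterminate_ids)
    if len(indeterminate_ids):
        warnings.append(
            f"{len(indeterminate_ids)} participants indeterminate at all visits "
            f"({criterion.name} never measured); excluded"
        )

    case_rows = (
        visits[is_case_visit]
        .drop_duplicates("participant_id", keep="first")
        .copy()
    )
    case_rows["case"] = True

    case_ids = set(case_rows["participant_id"])
    noncase_candidates = set(has_measure.index[has_measure]) - case_ids
    baseline = visits[visits["visit_index"].eq(1)]
    noncase_rows = baseline[baseline["participant_id"].isin(noncase_candidates)].copy()
    noncase_rows["case"] = False

    lost = noncase_candidates - set(noncase_rows["participant_id"])
    if lost:
        warnings.append(
            f"{len(lost)} noncase participants lack a baseline (visit 1) record; excluded"
        )
        exclusions.extend((pid, "noncase_without_baseline") for pid in sorted(lost))

    records = pd.concat([case_rows, noncase_rows], ignore_index=True)
    records = records.rename(columns={"visit_index": "index_visit"})
    records["hypertension_composite"] = hypertension_composite(records)
    records = _add_subgroup_labels(records)
    records = records.sort_values("participant_id", kind="mergesort").reset_index(drop=True)
    return AnalysisCohort(criterion, records, exclusions, warnings)


def complete_case_filter(cohort: AnalysisCohort, spec) -> AnalysisCohort:
    """Restrict to records with every predictor the score requires non-missing.

    Exclusion from missing data is model-specific, so each score is validated
    on its own complete-case cohort.
    """
    required = list(spec.required_predictors)
    unknown = [c for c in required if c not in cohort.records.columns]
    if unknown:
        raise ValueError(f"score {spec.name!r} requires unknown predictors {unknown}")
    mask = cohort.records[required].notna().all(axis=1)
    kept = cohort.records[mask].reset_index(drop=True)
    n_excluded = int((~mask).sum())
    out = cohort.with_records(
        kept,
        extra_warnings=[
            f"{spec.name}: {n_excluded} records excluded for missing predictors"
        ]
        if n_excluded
        else [],
    )
    dropped = cohort.records.loc[~mask, "participant_id"]
    out.exclusions.extend((pid, f"missing_predictor:{spec.name}") for pid in dropped)
    if out.n_total == 0 or out.n_cases == 0 or out.n_noncases == 0:
        raise ValueError(
            f"complete-case cohort for model {spec.name!r} has "
            f"{out.n_cases} cases and {out.n_noncases} noncases; cannot validate"
        )
    return out


#: stratification axes -> (label column, (stratum name for False, for True))
_AXES = {
    "sex": ("sex", ("male", "female")),
    "age_median": ("age_group", ("<median", ">=median")),
    "bmi_25": ("bmi_group", ("<25", ">=25")),
    "residency": ("residency", ("rural", "urban")),
}

MIN_STRATUM_CASES = 10


def stratify(cohort: AnalysisCohort, axis: str) -> dict[str, AnalysisCohort]:
    """Partition a cohort along one subgroup axis into its two strata.

    Records missing the axis variable are dropped with a warning, so the two
    strata plus the dropped records exhaust the input.  Strata with fewer
    than 10 cases carry a warning for downstream statistics.
    """
    if axis not in _AXES:
        raise ValueError(f"unknown stratification axis {axis!r}; one of {sorted(_AXES)}")
    column, strata = _AXES[axis]
    values = cohort.records[column]
    dropped = int(values.isna().sum())
    out: dict[str, AnalysisCohort] = {}
    for stratum in strata:
        sub = cohort.records[values.eq(stratum)].reset_index(drop=True)
        warns = []
        if dropped:
            warns.append(f"{dropped} records missing {column}; dropped from {axis} strata")
        n_cases = int(sub["case"].sum()) if len(sub) else 0
        if n_cases < MIN_STRATUM_CASES:
            warns.append(
                f"stratum {axis}={stratum} has {n_cases} cases (<{MIN_STRATUM_CASES}); "
                "downstream statistics unstable"
            )
        out[stratum] = cohort.with_records(sub, extra_warnings=warns)
    return out


@dataclass(frozen=True)
class MinEventsResult:
    status: str  # "pass" or "warn"
    n_cases: int
    n_noncases: int
    message: str


def check_min_events(cohort: AnalysisCohort, minimum: int = 100) -> MinEventsResult:
    """Check the 100-events / 100-nonevents precision rule for binary validation."""
    nc, nn = cohort.n_cases, cohort.n_noncases
    if nc >= minimum and nn >= minimum:
        return MinEventsResult("pass", nc, nn, f"{nc} cases and {nn} noncases")
    return MinEventsResult(
        "warn",
        nc,
        nn,
        f"below the recommended minimum of {minimum} events and {minimum} "
        f"non-events: {nc} cases, {nn} noncases",
    )


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a visit table CSV (missing values as empty strings)."""
    df = pd.read_csv(
        path,
        dtype={"participant_id": str},
        keep_default_na=True,
        na_values=[""],
    )
    missing_cols = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort CSV missing columns: {missing_cols}")
    for col in NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["visit_index"] = df["visit_index"].astype(int)
    return df[VISIT_COLUMNS]


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a visit table in the cohort CSV dialect (missing -> empty string)."""
    out = df[VISIT_COLUMNS].copy()
    out.to_csv(path, index=False, na_rep="")


def write_exclusion_log(cohort: AnalysisCohort, path) -> None:
    """Plain-text audit trail: one ``participant_id<TAB>reason`` line per exclusion."""
    buf = io.StringIO()
    for pid, reason in cohort.exclusions:
        buf.write(f"{pid}\t{reason}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
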