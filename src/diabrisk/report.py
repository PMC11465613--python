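"""Full validation grid: models x criteria x original/recalibrated x subgroups.

For each risk model and diagnostic criterion the pipeline assembles the
analysis dataset, applies the model-specific complete-case filter, checks
the 100-events precision rule, scores the cohort, computes discrimination
and calibration in the original state, recalibrates by intercept update,
recomputes calibration, and evaluates the subgroup grid (sex, median age,
BMI 25, residency) on the recalibrated probabilities.  Failures are recorded
per cell; remaining cells are still computed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import calibration as cal
from . import discrimination as disc
from .cohort import (
    AnalysisCohort,
    assemble_analysis_dataset,
    check_min_events,
    complete_case_filter,
    get_criterion,
    read_cohort_csv,
    stratify,
)
from .scores import ScoreSpec, load_score_spec, score_cohort

SUBGROUP_AXES = ("sex", "age_median", "bmi_25", "residency")


@dataclass
class ValidationCell:
    model: str
    criterion: str
    calibration_state: str  # "original" or "recalibrated"
    n: int
    cases: int
    eo: dict
    brier: float
    yates: float
    c: dict | None          # None for the recalibrated state (preserved by recalibration)
    c_note: str
    hl_chi2: float
    hl_p: float
    optimal_threshold: float
    sensitivity: float
    specificity: float
    top_left_threshold: float
    correction_factor: float | None
    warnings: list = field(default_factory=list)


@dataclass
class SubgroupCell:
    model: str
    criterion: str
    axis: str
    stratum: str
    n: int
    cases: int
    eo: dict
    c: dict
    p_compare: float | None
    warnings: list = field(default_factory=list)


@dataclass
class ValidationReport:
    meta: dict
    cells: list
    subgroup_cells: list
    errors: list
    warnings: list

    def to_dict(self) -> dict:
        return {
            "meta": self.meta,
            "cells": [dataclasses.asdict(c) for c in self.cells],
            "subgroup_cells": [dataclasses.asdict(c) for c in self.subgroup_cells],
            "errors": self.errors,
            "warnings": self.warnings,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ValidationReport":
        return cls(
            meta=payload["meta"],
            cells=[ValidationCell(**c) for c in payload["cells"]],
            subgroup_cells=[SubgroupCell(**c) for c in payload["subgroup_cells"]],
            errors=payload["errors"],
            warnings=payload["warnings"],
        )


def _eo_dict(e: cal.EORatio) -> dict:
    return {
        "expected": e.expected,
        "observed": e.observed,
        "ratio": e.ratio,
        "ci_low": e.ci_low,
        "ci_high": e.ci_high,
        "method": e.method,
    }


def _c_dict(c: disc.CStatResult) -> dict:
    return {
        "c": c.c,
        "se": c.se,
        "ci_low": c.ci_low,
        "ci_high": c.ci_high,
        "n_cases": c.n_cases,
        "n_noncases": c.n_noncases,
        "interpretation": disc.interpret_c(c.c),
    }


def _state_cell(
    model: str,
    criterion: str,
    state: str,
    probs: np.ndarray,
    labels: np.ndarray,
    hl_groups: int,
    c_result: disc.CStatResult | None,
    correction_factor: float | None,
    warnings: list,
) -> ValidationCell:
    roc = disc.roc_curve(probs, labels)
    youden = disc.youden_threshold(roc)
    top_left = disc.top_left_threshold(roc)
    hl = cal.hosmer_lemeshow(probs, labels, g=hl_groups)
    return ValidationCell(
        model=model,
        criterion=criterion,
        calibration_state=state,
        n=len(labels),
        cases=int(labels.sum()),
        eo=_eo_dict(cal.eo_ratio(probs, labels)),
        brier=cal.brier_score(probs, labels),
        yates=cal.yates_slope(probs, labels),
        c=_c_dict(c_result) if c_result is not None else None,
        c_note=(
            "" if state == "original"
            else "identical to the original state: intercept recalibration is "
                 "strictly monotone and cannot change discrimination"
        ),
        hl_chi2=hl.chi2,
        hl_p=hl.p_value,
        optimal_threshold=youden.threshold,
        sensitivity=youden.sensitivity,
        specificity=youden.specificity,
        top_left_threshold=top_left.threshold,
        correction_factor=correction_factor,
        warnings=list(warnings),
    )


def _subgroup_cells(
    model: str,
    criterion: str,
    cohort: AnalysisCohort,
    probs: np.ndarray,
    axes: Sequence[str],
    per_stratum_recalibration: bool,
) -> list[SubgroupCell]:
    scored = cohort.records.assign(_prob=probs)
    cells: list[SubgroupCell] = []
    for axis in axes:
        working = cohort.with_records(scored)
        strata = stratify(working, axis)
        results = {}
        for stratum, sub in strata.items():
            if sub.n_total == 0 or sub.n_cases == 0 or sub.n_noncases == 0:
                cells.append(
                    SubgroupCell(
                        model, criterion, axis, stratum,
                        sub.n_total, sub.n_cases if sub.n_total else 0,
                        eo={}, c={}, p_compare=None,
                        warnings=sub.warnings + ["degenerate stratum: one class empty"],
                    )
                )
                continue
            p = sub.records["_prob"].to_numpy()
            y = sub.records["case"].to_numpy(dtype=float)
            if per_stratum_recalibration:
                p = cal.apply_recalibration(p, None, labels=y).probabilities_after
            c_res = disc.c_statistic(p[y == 1], p[y == 0])
            results[stratum] = (sub, p, y, c_res)
        if len(results) == 2:
            (s1, (sub1, p1, y1, c1)), (s2, (sub2, p2, y2, c2)) = results.items()
            _, p_cmp = disc.compare_c_independent(c1, c2)
        else:
            p_cmp = None
        for stratum, (sub, p, y, c_res) in results.items():
            cells.append(
                SubgroupCell(
                    model=model,
                    criterion=criterion,
                    axis=axis,
                    stratum=stratum,
                    n=sub.n_total,
                    cases=sub.n_cases,
                    eo=_eo_dict(cal.eo_ratio(p, y)),
                    c=_c_dict(c_res),
                    p_compare=p_cmp,
                    warnings=list(sub.warnings),
                )
            )
    return cells


def validate_model_criterion(
    visits: pd.DataFrame,
    spec: ScoreSpec,
    criterion_name: str,
    recalibrate_mode: str = "one_step",
    hl_groups: int = 10,
    axes: Sequence[str] = SUBGROUP_AXES,
    subgroups_on_original: bool = False,
    per_stratum_recalibration: bool = False,
) -> tuple[list[ValidationCell], list[SubgroupCell], list[str]]:
    """One model x criterion column of the grid (both calibration states)."""
    criterion = get_criterion(criterion_name)
    cohort = assemble_analysis_dataset(visits, criterion)
    cohort = complete_case_filter(cohort, spec)
    warnings = list(cohort.warnings)
    min_events = check_min_events(cohort)
    if min_events.status == "warn":
        warnings.append(f"min-events: {min_events.message}")

    scored = score_cohort(spec, cohort)
    probs = scored["probability"].to_numpy()
    labels = scored["case"].to_numpy(dtype=float)
    c_res = disc.c_statistic(probs[labels == 1], probs[labels == 0])

    recal = cal.apply_recalibration(probs, None, labels=labels, mode=recalibrate_mode)
    cells = [
        _state_cell(
            spec.name, criterion.name, "original", probs, labels,
            hl_groups, c_res, None, warnings,
        ),
        _state_cell(
            spec.name, criterion.name, "recalibrated",
            recal.probabilities_after, labels, hl_groups, None,
            recal.correction_factor, warnings,
        ),
    ]
    sub_probs = probs if subgroups_on_original else recal.probabilities_after
    subgroups = _subgroup_cells(
        spec.name, criterion.name, cohort, sub_probs, axes, per_stratum_recalibration
    )
    return cells, subgroups, warnings


def run_validation(
    cohort: pd.DataFrame | str,
    score_specs: Sequence[ScoreSpec | str],
    criteria: Sequence[str] = ("FPG", "HBA1C"),
    recalibrate_mode: str = "one_step",
    hl_groups: int = 10,
    axes: Sequence[str] = SUBGROUP_AXES,
    subgroups_on_original: bool = False,
    per_stratum_recalibration: bool = False,
) -> ValidationReport:
    """Run the full validation grid; per-cell failures do not stop the run."""
    visits = read_cohort_csv(cohort) if isinstance(cohort, str) else cohort
    specs = [
        s if isinstance(s, ScoreSpec) else load_score_spec(s) for s in score_specs
    ]
    if not specs:
        raise ValueError("at least one score spec is required")

    cells: list[ValidationCell] = []
    subgroup_cells: list[SubgroupCell] = []
    errors: list[dict] = []
    warnings: list[str] = []
    for spec in specs:
        for crit in criteria:
            try:
                c, s, w = validate_model_criterion(
                    visits,
                    spec,
                    crit,
                    recalibrate_mode=recalibrate_mode,
                    hl_groups=hl_groups,
                    axes=axes,
                    subgroups_on_original=subgroups_on_original,
                    per_stratum_recalibration=per_stratum_recalibration,
                )
                cells.extend(c)
                subgroup_cells.extend(s)
                warnings.extend(f"{spec.name}/{crit}: {msg}" for msg in w)
            except Exception as exc:  # per-cell failure: record and continue
                errors.append({"model": spec.name, "criterion": crit, "error": str(exc)})
    return ValidationReport(
        meta={
            "models": [s.name for s in specs],
            "criteria": list(criteria),
            "recalibrate_mode": recalibrate_mode,
            "hl_groups": hl_groups,
            "axes": list(axes),
            "subgroups_on_original": subgroups_on_original,
            "per_stratum_recalibration": per_stratum_recalibration,
            "n_input_rows": int(len(visits)),
        },
        cells=cells,
        subgroup_cells=subgroup_cells,
        errors=errors,
        warnings=warnings,
    )


def _round(x, nd):
    return None if x is None else round(float(x), nd)


def cells_frame(report: ValidationReport, rounded: bool = True) -> pd.DataFrame:
    """Flatten validation cells, one row each, with report-style rounding."""
    rows = []
    for cell in report.cells:
        row = {
            "model": cell.model,
            "criterion": cell.criterion,
            "calibration_state": cell.calibration_state,
            "n": cell.n,
            "cases": cell.cases,
            "eo_ratio": cell.eo["ratio"],
            "eo_ci_low": cell.eo["ci_low"],
            "eo_ci_high": cell.eo["ci_high"],
            "brier": cell.brier,
            "yates": cell.yates,
            "c": cell.c["c"] if cell.c else None,
            "c_ci_low": cell.c["ci_low"] if cell.c else None,
            "c_ci_high": cell.c["ci_high"] if cell.c else None,
            "optimal_threshold": cell.optimal_threshold,
            "sensitivity": cell.sensitivity,
            "specificity": cell.specificity,
            "hl_p": cell.hl_p,
            "correction_factor": cell.correction_factor,
            "warnings": "; ".join(cell.warnings),
        }
        if rounded:
            for key in ("eo_ratio", "eo_ci_low", "eo_ci_high", "c", "c_ci_low",
                        "c_ci_high", "optimal_threshold", "brier", "yates"):
                row[key] = _round(row[key], 2)
            for key in ("sensitivity", "specificity"):
                row[key] = _round(row[key], 1)
        rows.append(row)
    return pd.DataFrame(rows)


def subgroups_frame(report: ValidationReport, rounded: bool = True) -> pd.DataFrame:
    rows = []
    for cell in report.subgroup_cells:
        row = {
            "model": cell.model,
            "criterion": cell.criterion,
            "axis": cell.axis,
            "stratum": cell.stratum,
            "n": cell.n,
            "cases": cell.cases,
            "eo_ratio": cell.eo.get("ratio"),
            "eo_ci_low": cell.eo.get("ci_low"),
            "eo_ci_high": cell.eo.get("ci_high"),
            "c": cell.c.get("c"),
            "c_ci_low": cell.c.get("ci_low"),
            "c_ci_high": cell.c.get("ci_high"),
            "p_compare": cell.p_compare,
            "warnings": "; ".join(cell.warnings),
        }
        if rounded:
            for key in ("eo_ratio", "eo_ci_low", "eo_ci_high", "c", "c_ci_low",
                        "c_ci_high", "p_compare"):
                row[key] = _round(row[key], 2)
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(report: ValidationReport, fmt: str, path: str) -> list[str]:
    """Serialise a report: lossless JSON or flattened (rounded) CSV tables."""
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
            fh.write("\n")
        return [path]
    if fmt == "csv":
        base = path[:-4] if path.endswith(".csv") else path
        cells_path = f"{base}_cells.csv"
        sub_path = f"{base}_subgroups.csv"
        cells_frame(report).to_csv(cells_path, index=False)
        subgroups_frame(report).to_csv(sub_path, index=False)
        return [cells_path, sub_path]
    raise ValueError(f"unknown report format {fmt!r}")


def read_report(path: str) -> ValidationReport:
    with open(path) as fh:
        return ValidationReport.from_dict(json.load(fh))
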