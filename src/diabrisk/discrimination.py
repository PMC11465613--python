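"""Discrimination statistics: C-statistic, ROC curve and optimal thresholds.

The C-statistic is the probability that a randomly chosen case carries a
higher predicted risk than a randomly chosen noncase (ties counted half); it
equals the trapezoidal area under the ROC polyline.  Its standard error uses
the nonparametric structural-components (DeLong) estimator, which also
supports comparing C between disjoint subgroups with an independent-samples
z-test.

Classification convention throughout: positive iff probability >= threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class CStatResult:
    c: float
    se: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_noncases: int


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class ThresholdResult:
    method: str  # "youden" or "top_left"
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent
    j: float


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def c_statistic(probs_cases, probs_noncases) -> CStatResult:
    """Concordance statistic with DeLong structural-components variance.

    c = (#{case > noncase} + 0.5 * #{ties}) / (n_cases * n_noncases),
    computed via midranks; the 95% CI is c +/- 1.96*se truncated to [0, 1].
    """
    x = np.asarray(probs_cases, dtype=float)
    y = np.asarray(probs_noncases, dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both cases and noncases must be non-empty")

    combined = np.concatenate([x, y])
    r_all = _midranks(combined)
    r_x = _midranks(x)
    r_y = _midranks(y)
    # structural components (Sun & Xu midrank formulation)
    v10 = (r_all[:m] - r_x) / n               # per-case component
    v01 = 1.0 - (r_all[m:] - r_y) / m         # per-noncase component
    # single division of an exactly representable numerator: identical to the
    # pair-count formula (#{case > noncase} + 0.5 * #{ties}) / (m * n)
    c = float((r_all[:m].sum() - m * (m + 1) / 2) / (m * n))

    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    lo = max(0.0, c - _Z95 * se)
    hi = min(1.0, c + _Z95 * se)
    return CStatResult(c, se, lo, hi, m, n)


def roc_curve(probs, labels) -> list[RocPoint]:
    """ROC polyline: one point per distinct probability plus the (0, 1) endpoint.

    Points are ordered by increasing threshold; the first point (threshold =
    lowest observed probability) is the all-positive corner (sens 1, spec 0)
    and the final +inf threshold is the all-negative corner (sens 0, spec 1).
    The trapezoidal area under the polyline equals the C-statistic.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(p) == 0 or len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    m = int(y.sum())
    n = len(y) - m

    thresholds = np.unique(p)
    cases_sorted = np.sort(p[y == 1])
    nons_sorted = np.sort(p[y == 0])
    # counts of cases / noncases with prob >= t for each distinct t
    case_counts = m - np.searchsorted(cases_sorted, thresholds, side="left")
    non_counts = n - np.searchsorted(nons_sorted, thresholds, side="left")
    points = [
        RocPoint(float(t), ck / m, 1.0 - cn / n)
        for t, ck, cn in zip(thresholds, case_counts, non_counts)
    ]
    points.append(RocPoint(float("inf"), 0.0, 1.0))
    return points


def roc_auc(roc: list[RocPoint]) -> float:
    """Trapezoidal area under a :func:`roc_curve` polyline."""
    sens = np.array([pt.sensitivity for pt in roc])
    fpr = np.array([1.0 - pt.specificity for pt in roc])
    # thresholds ascend, so fpr descends from 1 to 0
    return float(np.trapezoid(sens[::-1], fpr[::-1]))


def _finite_points(roc: list[RocPoint]) -> list[RocPoint]:
    return [pt for pt in roc if np.isfinite(pt.threshold)]


def youden_threshold(roc: list[RocPoint]) -> ThresholdResult:
    """Maximise J = sensitivity + specificity - 1 over observed thresholds.

    Ties resolve to the lowest threshold.  J is 1 at complete separation and
    0 at complete overlap.
    """
    best = None
    for pt in _finite_points(roc):
        j = pt.sensitivity + pt.specificity - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, pt)
    j, pt = best
    return ThresholdResult(
        "youden", pt.threshold, 100.0 * pt.sensitivity, 100.0 * pt.specificity, j
    )


def top_left_threshold(roc: list[RocPoint]) -> ThresholdResult:
    """Minimise the Euclidean distance to the perfect (sens 1, spec 1) corner."""
    best = None
    for pt in _finite_points(roc):
        d = np.hypot(1.0 - pt.sensitivity, 1.0 - pt.specificity)
        if best is None or d < best[0] - 1e-12:
            best = (d, pt)
    _, pt = best
    return ThresholdResult(
        "top_left",
        pt.threshold,
        100.0 * pt.sensitivity,
        100.0 * pt.specificity,
        pt.sensitivity + pt.specificity - 1.0,
    )


def sens_spec_at(probs, labels, threshold: float) -> tuple[float, float]:
    """Sensitivity and specificity (percent, 1 decimal) at one threshold."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = p >= threshold
    m = int(y.sum())
    n = len(y) - m
    sens = 100.0 * (pos & (y == 1)).sum() / m if m else float("nan")
    spec = 100.0 * (~pos & (y == 0)).sum() / n if n else float("nan")
    return round(sens, 1), round(spec, 1)


def compare_c_independent(a: CStatResult, b: CStatResult) -> tuple[float, float]:
    """Two-sided z-test comparing C between two disjoint subgroups."""
    denom = np.sqrt(a.se**2 + b.se**2)
    if denom == 0:
        if a.c == b.c:
            return 0.0, 1.0
        return float("inf") * np.sign(a.c - b.c), 0.0
    z = (a.c - b.c) / denom
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def interpret_c(c: float) -> str:
    """Conventional discrimination bands (lower-inclusive)."""
    if not 0.0 <= c <= 1.0:
        raise ValueError("C-statistic must lie in [0, 1]")
    if c >= 0.9:
        return "excellent"
    if c >= 0.8:
        return "good"
    if c >= 0.7:
        return "acceptable"
    return "poor"


def roc_table(roc: list[RocPoint]):
    """ROC points as a DataFrame (threshold, sensitivity, specificity) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "threshold": [pt.threshold for pt in roc],
            "sensitivity": [pt.sensitivity for pt in roc],
            "specificity": [pt.specificity for pt in roc],
        }
    )
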