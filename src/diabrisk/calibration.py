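"""Calibration statistics and intercept recalibration.

Calibration is the agreement between predicted probabilities and observed
outcome frequencies.  Summary measures: the expected/observed (E/O) ratio
with Poisson confidence intervals (>1 overestimation, <1 underestimation),
the Brier score (mean squared error of the probability forecast; 0 is
perfect), the Yates/discrimination slope (difference in mean predicted risk
between cases and noncases), the Hosmer-Lemeshow goodness-of-fit chi-square
on risk deciles, and binned calibration-curve tables.

Recalibration follows the intercept-update approach: every predicted
probability is shifted on the log-odds scale by a single correction factor
Delta = ln[odds(observed prevalence) / odds(mean predicted risk)].  Being a
strictly monotone map, this never changes discrimination.  The one-step
update is the default; an iterated mode repeats the update to a fixed point
at which expected and observed case counts agree to machine-level tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, TransformerMixin

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class EORatio:
    expected: float
    observed: int
    ratio: float
    ci_low: float
    ci_high: float
    method: str = "lognormal"  # or "exact_poisson"

    @property
    def direction(self) -> str:
        if self.ratio > 1.0:
            return "overestimation"
        if self.ratio < 1.0:
            return "underestimation"
        return "ideal"


@dataclass(frozen=True)
class CalibrationBin:
    bin_index: int
    n: int
    mean_predicted: float
    observed_rate: float
    cases: int


@dataclass(frozen=True)
class HLResult:
    chi2: float
    df: int
    p_value: float
    n_bins: int


@dataclass
class RecalibrationResult:
    correction_factor: float
    probabilities_before: np.ndarray
    probabilities_after: np.ndarray
    mode: str
    n_iter: int = 1


def _as_arrays(probs, labels=None):
    p = np.asarray(probs, dtype=float)
    if labels is None:
        return p
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probs and labels must have equal length")
    return p, y


def brier_score(probs, labels) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p, y = _as_arrays(probs, labels)
    if len(p) == 0:
        raise ValueError("empty input")
    return float(np.mean((p - y) ** 2))


def yates_slope(probs, labels) -> float:
    """Mean predicted risk in cases minus mean predicted risk in noncases."""
    p, y = _as_arrays(probs, labels)
    if not (y == 1).any() or not (y == 0).any():
        raise ValueError("both classes required for the Yates slope")
    return float(p[y == 1].mean() - p[y == 0].mean())


def eo_ratio(probs, labels, exact: bool = False) -> EORatio:
    """Expected/observed case ratio with a 95% Poisson CI on the observed count.

    Default CI is the log-normal approximation ratio * exp(-/+ 1.96/sqrt(O));
    ``exact=True`` uses exact Poisson limits for O via the chi-square link.
    """
    p, y = _as_arrays(probs, labels)
    expected = float(p.sum())
    observed = int(round(float(y.sum())))
    if observed < 1:
        raise ValueError("E/O ratio undefined with zero observed cases")
    ratio = expected / observed
    if exact:
        o_lo = stats.chi2.ppf(0.025, 2 * observed) / 2.0
        o_hi = stats.chi2.ppf(0.975, 2 * observed + 2) / 2.0
        return EORatio(
            expected, observed, ratio, expected / o_hi, expected / o_lo,
            method="exact_poisson",
        )
    half = _Z95 / np.sqrt(observed)
    return EORatio(expected, observed, ratio, ratio * np.exp(-half), ratio * np.exp(half))


def _quantile_bins(p: np.ndarray, g: int) -> np.ndarray:
    """Quantile bin index per observation; tied boundaries merge bins."""
    if g == 1:
        return np.zeros(len(p), dtype=int)
    codes = pd.qcut(p, g, labels=False, duplicates="drop")
    codes = np.nan_to_num(np.asarray(codes, dtype=float), nan=0.0)  # constant input
    return codes.astype(int)


def calibration_bins(probs, labels, g: int = 10) -> list[CalibrationBin]:
    """Quantile-binned calibration-curve table (mean predicted vs observed rate)."""
    p, y = _as_arrays(probs, labels)
    if len(p) < g:
        raise ValueError(f"need at least g={g} observations")
    codes = _quantile_bins(p, g)
    bins = []
    for i in range(codes.max() + 1):
        mask = codes == i
        n = int(mask.sum())
        bins.append(
            CalibrationBin(
                bin_index=i,
                n=n,
                mean_predicted=float(p[mask].mean()),
                observed_rate=float(y[mask].mean()),
                cases=int(y[mask].sum()),
            )
        )
    bins.sort(key=lambda b: b.mean_predicted)
    return bins


def hosmer_lemeshow(probs, labels, g: int = 10) -> HLResult:
    """Hosmer-Lemeshow chi-square on deciles of predicted risk.

    chi2 = sum_b (O_b - E_b)^2 / (E_b (1 - pbar_b)) with pbar_b the bin mean
    predicted probability.  Degrees of freedom equal the number of bins: the
    probabilities under validation are fully pre-specified (no parameters are
    refit on these data), so no degrees are lost to estimation.
    """
    p, y = _as_arrays(probs, labels)
    if not (y == 1).any() or not (y == 0).any():
        raise ValueError("both classes required")
    codes = _quantile_bins(p, g)
    n_bins = int(codes.max() + 1)
    if n_bins < 3:
        raise ValueError(f"only {n_bins} usable bins after merging tied boundaries")
    chi2 = 0.0
    for i in range(n_bins):
        mask = codes == i
        e = float(p[mask].sum())
        o = float(y[mask].sum())
        pbar = float(p[mask].mean())
        denom = e * (1.0 - pbar)
        if denom <= 0:
            continue
        chi2 += (o - e) ** 2 / denom
    df = n_bins
    return HLResult(float(chi2), df, float(stats.chi2.sf(chi2, df)), n_bins)


def recalibration_factor(probs, labels) -> float:
    """Intercept-update correction factor.

    The natural logarithm of the odds ratio of the observed prevalence to the
    mean predicted risk: Delta = ln[odds(prev) / odds(pbar)].
    """
    p, y = _as_arrays(probs, labels)
    prev = float(y.mean())
    pbar = float(p.mean())
    if not (0.0 < prev < 1.0 and 0.0 < pbar < 1.0):
        raise ValueError("prevalence and mean predicted risk must lie strictly in (0,1)")
    return float(logit(prev) - logit(pbar))


def apply_recalibration(
    probs,
    correction_factor: float | None = None,
    labels=None,
    mode: str = "one_step",
    tol: float = 1e-6,
    max_iter: int = 100,
) -> RecalibrationResult:
    """Shift predicted probabilities by a constant on the log-odds scale.

    ``one_step`` applies the given (or computed) factor once.  ``iterated``
    repeats compute-factor-then-apply until |sum(p') - sum(y)| < tol * n,
    accumulating the total shift; this drives E/O to 1 on the data the factor
    is computed from.  Probability ranking is preserved in either mode.
    """
    p = np.asarray(probs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0,1)")
    if correction_factor is None:
        if labels is None:
            raise ValueError("need either a correction_factor or labels")
        correction_factor = recalibration_factor(p, labels)

    if mode == "one_step":
        p_new = expit(logit(p) + correction_factor)
        return RecalibrationResult(float(correction_factor), p, p_new, mode, 1)
    if mode != "iterated":
        raise ValueError(f"unknown recalibration mode {mode!r}")
    if labels is None:
        raise ValueError("iterated recalibration requires labels")
    y = np.asarray(labels, dtype=float)
    total = 0.0
    p_new = p
    for it in range(1, max_iter + 1):
        delta = recalibration_factor(p_new, y)
        total += delta
        p_new = expit(logit(p) + total)
        if abs(p_new.sum() - y.sum()) < tol * len(p):
            return RecalibrationResult(float(total), p, p_new, mode, it)
    raise RuntimeError(f"iterated recalibration did not converge in {max_iter} iterations")


class InterceptRecalibrator(BaseEstimator, TransformerMixin):
    """Intercept-update recalibrator with the scikit-learn fit/transform API.

    ``fit`` learns a single log-odds shift from predicted probabilities and
    observed outcomes; ``transform`` applies it to any probability vector.

    Parameters
    ----------
    mode : {"one_step", "iterated"}
        One-step uses the closed-form correction factor; iterated refines it
        to a fixed point where expected equals observed on the fitting data.
    tol, max_iter : convergence control for the iterated mode.

    Attributes
    ----------
    correction_factor_ : float
        Total log-odds shift learned by ``fit``.
    n_iter_ : int
        Update steps performed.
    """

    def __init__(self, mode: str = "one_step", tol: float = 1e-6, max_iter: int = 100):
        self.mode = mode
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        p = np.asarray(X, dtype=float).reshape(-1)
        result = apply_recalibration(
            p, None, labels=y, mode=self.mode, tol=self.tol, max_iter=self.max_iter
        )
        self.correction_factor_ = result.correction_factor
        self.n_iter_ = result.n_iter
        return self

    def transform(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "correction_factor_")
        p = np.asarray(X, dtype=float).reshape(-1)
        return np.asarray(expit(logit(p) + self.correction_factor_))


def calibration_table(bins: list[CalibrationBin]) -> pd.DataFrame:
    """Calibration bins as a DataFrame for CSV export."""
    return pd.DataFrame([b.__dict__ for b in bins])
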