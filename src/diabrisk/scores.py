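"""Declarative risk-score engine.

Each risk model (ADRS, Simplified FINDRISC, ADA, IRS, or any user-supplied
score) is a :class:`ScoreSpec`: a list of items that map predictors to points
or coefficients, plus a link that turns the total into a probability of
prevalent undiagnosed type-2 diabetes.  Point-based scores carry a
``score_logistic`` link p = 1/(1+exp(-(a + b*s))) whose parameters are part
of the spec file, so the engine itself is model-agnostic; logistic-form
scores use their linear predictor directly.

Category intervals are lower-inclusive half-open ``[lo, hi)``, matching the
">=" convention of the diagnostic thresholds.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_right
from importlib import resources
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit
from sklearn.base import BaseEstimator

from .cohort import VISIT_COLUMNS

#: predictors a spec may reference: visit fields plus derived columns
KNOWN_PREDICTORS = set(VISIT_COLUMNS) | {"hypertension_composite"}


class MissingPredictorError(ValueError):
    """A record lacks a predictor the score requires (not-applicable signal)."""


class ScoreItem(BaseModel):
    model_config = ConfigDict(extra="forbid")

    predictor: str
    kind: Literal["threshold_points", "categorical_points", "linear_coefficient"]
    cut_points: list[float] | None = None
    values: list[float] | dict[str, float] | None = None
    coefficient: float | None = None
    sex_specific: dict[str, list[float]] | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.predictor not in KNOWN_PREDICTORS:
            raise ValueError(f"unknown predictor {self.predictor!r}")
        if self.kind == "threshold_points":
            if not self.cut_points:
                raise ValueError(f"{self.predictor}: threshold_points needs cut_points")
            if any(b <= a for a, b in zip(self.cut_points, self.cut_points[1:])):
                raise ValueError(
                    f"{self.predictor}: cut_points must be strictly increasing"
                )
            if not isinstance(self.values, list):
                raise ValueError(f"{self.predictor}: interval values must be a list")
            if len(self.values) != len(self.cut_points) + 1:
                raise ValueError(
                    f"{self.predictor}: need {len(self.cut_points) + 1} interval "
                    f"values, got {len(self.values)}"
                )
            if self.sex_specific is not None:
                for sex, cuts in self.sex_specific.items():
                    if len(cuts) != len(self.cut_points):
                        raise ValueError(
                            f"{self.predictor}: sex_specific cut_points for {sex!r} "
                            "must match the default cut count"
                        )
        elif self.kind == "categorical_points":
            if not isinstance(self.values, dict) or not self.values:
                raise ValueError(
                    f"{self.predictor}: categorical_points needs a category->value map"
                )
        else:  # linear_coefficient
            if self.coefficient is None:
                raise ValueError(f"{self.predictor}: linear_coefficient needs coefficient")
        return self


class ProbabilityLink(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["direct_logistic", "score_logistic"]
    a: float = 0.0
    b: float = 1.0

    @model_validator(mode="after")
    def _check(self):
        if self.kind == "score_logistic" and self.b <= 0:
            raise ValueError("score_logistic slope b must be positive")
        return self


class ScoreSpec(BaseModel):
    """Declarative definition of one risk prediction model."""

    model_config = ConfigDict(extra="forbid")

    name: str
    form: Literal["points", "logistic"]
    items: list[ScoreItem] = Field(min_length=1)
    intercept: float = 0.0
    probability_link: ProbabilityLink
    description: str = ""
    citation: str = ""
    provisional: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.form == "logistic" and self.probability_link.kind != "direct_logistic":
            raise ValueError("logistic-form scores use the direct_logistic link")
        return self

    @property
    def required_predictors(self) -> list[str]:
        """Predictors that must be non-missing for this score (complete case)."""
        req = []
        for item in self.items:
            if item.predictor not in req:
                req.append(item.predictor)
            if item.sex_specific and "sex" not in req:
                req.append("sex")
        return req


def _category_key(value) -> str:
    """Normalise a record value to a spec category key.

    Numeric categories (e.g. ordinal physical-activity levels stored as
    floats) are keyed by their integer representation.
    """
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        if float(value).is_integer():
            return str(int(value))
        return str(float(value))
    return str(value)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, (float, np.floating)):
        return math.isnan(value)
    return pd.isna(value)


def _item_value(item: ScoreItem, record: Mapping) -> float:
    value = record.get(item.predictor) if hasattr(record, "get") else record[item.predictor]
    if _is_missing(value):
        raise MissingPredictorError(
            f"predictor {item.predictor!r} missing; score not applicable"
        )
    if item.kind == "linear_coefficient":
        return item.coefficient * float(value)
    if item.kind == "categorical_points":
        key = _category_key(value)
        try:
            return item.values[key]
        except KeyError:
            raise ValueError(
                f"value {value!r} of {item.predictor!r} not among categories "
                f"{sorted(item.values)}"
            )
    # threshold_points: lower-inclusive half-open intervals
    cuts = item.cut_points
    if item.sex_specific:
        sex = record.get("sex") if hasattr(record, "get") else record["sex"]
        if _is_missing(sex):
            raise MissingPredictorError(
                f"predictor 'sex' missing but {item.predictor!r} uses sex-specific cuts"
            )
        cuts = item.sex_specific.get(str(sex), cuts)
    return item.values[bisect_right(cuts, float(value))]


def evaluate_score(spec: ScoreSpec, record: Mapping) -> float:
    """Raw score of one record: sum of points, or the logistic linear predictor.

    Raises :class:`MissingPredictorError` when a required predictor is
    missing — never substitutes a default value.
    """
    total = sum(_item_value(item, record) for item in spec.items)
    if spec.form == "logistic":
        total += spec.intercept
    return float(total)


def score_to_probability(spec: ScoreSpec, raw_score) -> float | np.ndarray:
    """Map a raw score to P(prevalent undiagnosed T2D), strictly increasing."""
    raw = np.asarray(raw_score, dtype=float)
    link = spec.probability_link
    if link.kind == "direct_logistic":
        p = expit(raw)
    else:
        p = expit(link.a + link.b * raw)
    return float(p) if np.isscalar(raw_score) else p


def _item_values_vector(item: ScoreItem, df: pd.DataFrame) -> np.ndarray:
    col = df[item.predictor]
    if col.isna().any():
        bad = df.loc[col.isna(), "participant_id"].tolist()[:5]
        raise MissingPredictorError(
            f"predictor {item.predictor!r} missing for participants {bad}..."
        )
    if item.kind == "linear_coefficient":
        return item.coefficient * col.to_numpy(dtype=float)
    if item.kind == "categorical_points":
        mapped = col.map(lambda v: item.values[_category_key(v)])
        return mapped.to_numpy(dtype=float)
    values = np.asarray(item.values, dtype=float)
    x = col.to_numpy(dtype=float)
    if item.sex_specific:
        out = np.empty(len(df), dtype=float)
        sex = df["sex"]
        if sex.isna().any():
            raise MissingPredictorError(
                f"predictor 'sex' missing but {item.predictor!r} uses sex-specific cuts"
            )
        for s in sex.unique():
            cuts = np.asarray(item.sex_specific.get(str(s), item.cut_points), float)
            mask = sex.eq(s).to_numpy()
            out[mask] = values[np.searchsorted(cuts, x[mask], side="right")]
        return out
    cuts = np.asarray(item.cut_points, dtype=float)
    return values[np.searchsorted(cuts, x, side="right")]


def score_frame(spec: ScoreSpec, records: pd.DataFrame) -> pd.DataFrame:
    """Vectorised scoring of a record table.

    Returns a frame with ``participant_id``, ``raw_score`` and ``probability``
    (plus ``case`` when present), order-preserving.
    """
    if len(records) == 0:
        return pd.DataFrame(
            columns=["participant_id", "raw_score", "probability", "case"]
        )
    raw = np.zeros(len(records), dtype=float)
    for item in spec.items:
        raw += _item_values_vector(item, records)
    if spec.form == "logistic":
        raw += spec.intercept
    out = pd.DataFrame(
        {
            "participant_id": records["participant_id"].to_numpy(),
            "raw_score": raw,
            "probability": score_to_probability(spec, raw),
        }
    )
    if "case" in records.columns:
        out["case"] = records["case"].to_numpy()
    return out


def score_cohort(spec: ScoreSpec, cohort) -> pd.DataFrame:
    """Score every record of an (already complete-case filtered) cohort."""
    return score_frame(spec, cohort.records)


class RiskScore(BaseEstimator):
    """A fixed risk prediction model as a scikit-learn style classifier.

    The coefficients are frozen configuration (``fit`` performs validation
    only; nothing is estimated from data), so the estimator can sit in
    pipelines and be cross-validated against refit models without ever
    refitting itself.

    Parameters
    ----------
    spec : ScoreSpec or path
        The declarative score definition.
    threshold : float
        Probability cut-off used by :meth:`predict`.
    """

    def __init__(self, spec=None, threshold: float = 0.5):
        self.spec = spec
        self.threshold = threshold

    def fit(self, X=None, y=None):
        spec = self.spec
        if isinstance(spec, (str,)) or hasattr(spec, "__fspath__"):
            spec = load_score_spec(spec)
        if not isinstance(spec, ScoreSpec):
            spec = ScoreSpec.model_validate(spec)
        self.spec_ = spec
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "spec_")
        frame = X if "participant_id" in X.columns else X.assign(participant_id="")
        return score_frame(self.spec_, frame)["raw_score"].to_numpy()

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = score_to_probability(self.spec_, self.decision_function(X))
        p = np.asarray(p, dtype=float)
        return np.column_stack([1 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)


def load_score_spec(path) -> ScoreSpec:
    """Load and validate a score-spec file (JSON or YAML by extension)."""
    text = open(path).read()
    if str(path).endswith((".yaml", ".yml")):
        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return ScoreSpec.model_validate(payload)


def save_score_spec(spec: ScoreSpec, path) -> None:
    """Serialise a spec; round-trips bit-exactly through :func:`load_score_spec`."""
    payload = spec.model_dump(exclude_none=True)
    with open(path, "w") as fh:
        if str(path).endswith((".yaml", ".yml")):
            yaml.safe_dump(payload, fh, sort_keys=False)
        else:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


BUNDLED_SPECS = ("adrs", "simplified_findrisc", "ada", "irs")


def bundled_spec(name: str) -> ScoreSpec:
    """Load one of the four bundled (provisional) score transcriptions."""
    key = name.lower()
    if key not in BUNDLED_SPECS:
        raise ValueError(f"no bundled spec {name!r}; one of {BUNDLED_SPECS}")
    ref = resources.files("diabrisk") / "specs" / f"{key}.json"
    return ScoreSpec.model_validate(json.loads(ref.read_text()))


def bundled_spec_paths() -> dict[str, str]:
    root = resources.files("diabrisk") / "specs"
    return {name: str(root / f"{name}.json") for name in BUNDLED_SPECS}
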