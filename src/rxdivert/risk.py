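"""Transaction-level diversion risk: scores, percentile labels, classifiers.

The pipeline assigns every movement transaction a numeric risk score (a
weighted sum of its one-hot flags), labels the top tail of the score
distribution as *high risk* (98th percentile by default, nearest-rank), and
then trains a supervised classifier — logistic regression or random forest —
to reproduce that labeling from the flags alone.  Training uses a stratified
60/40 split with seeded shuffling, random-duplication oversampling of the
minority class *in the training split only*, and stratified K-fold
cross-validation on the training data; final metrics come from the held-out
40%.

The default weights order the flags by how directly each behavior maps to
diversion (whole-dose discrepancies and supply shortfalls highest, timing
and practice anomalies lower); they shape the score ordering only — the
operative threshold is the percentile, not the absolute scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import FEATURE_ORDER

DEFAULT_WEIGHTS = {
    "full_wasting": 5.0,
    "no_administration": 5.0,
    "shipment_shortfall": 5.0,
    "restock_shortfall": 5.0,
    "off_clock_access": 4.0,
    "bulk_wasting": 4.0,
    "incorrect_medication": 4.0,
    "partial_administration": 3.0,
    "partial_waste_return": 3.0,
    "late_wasting": 2.0,
    "late_administration": 2.0,
    "incorrect_order": 2.0,
    "handoffs": 1.0,
    "pain_score_anomaly": 1.0,
}

MIN_SCORES_FOR_PERCENTILE = 50


class RiskParams(BaseModel):
    """Scoring, labeling and training configuration."""

    weights: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    percentile: float = 98.0
    train_fraction: float = 0.60
    k_folds: int = 5
    oversample: bool = True
    classifier: str = "logistic_regression"  # or "random_forest"
    percentile_over: str = "all"  # or "nonzero"
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "RiskParams":
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.classifier not in ("logistic_regression", "random_forest"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.percentile_over not in ("all", "nonzero"):
            raise ValueError("percentile_over must be 'all' or 'nonzero'")
        missing = [c for c in FEATURE_ORDER if c not in self.weights]
        if missing:
            raise ValueError(f"weights missing for features: {missing}")
        for name, w in self.weights.items():
            if w < 0:
                raise ValueError(f"weight for {name} must be nonnegative")
        return self


# --------------------------------------------------------------------------
# Scoring and labeling
# --------------------------------------------------------------------------

def score(features, weights: dict[str, float] | None = None) -> np.ndarray:
    """Risk score per row: the weighted sum of its binary flags."""
    weights = weights if weights is not None else DEFAULT_WEIGHTS
    missing = [c for c in FEATURE_ORDER if c not in weights]
    if missing:
        raise KeyError(f"missing weight for features: {missing}")
    if isinstance(features, pd.DataFrame):
        matrix = features[FEATURE_ORDER].to_numpy(dtype=float)
    else:
        matrix = np.asarray(features, dtype=float)
        if matrix.shape[1] != len(FEATURE_ORDER):
            raise ValueError("feature matrix has wrong column count")
    w = np.array([weights[c] for c in FEATURE_ORDER])
    return matrix @ w


def label_high_risk(
    scores: np.ndarray,
    percentile: float = 98.0,
    percentile_over: str = "all",
) -> tuple[np.ndarray, float]:
    """High-risk labels by the empirical percentile (nearest-rank, 'higher').

    Returns ``(labels, threshold)``; a row is high iff its score >= the
    threshold, so ties at the threshold are all labeled high.  With
    ``percentile_over='nonzero'`` the percentile is computed over the
    nonzero scores only (the threshold still applies to every row).
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) < MIN_SCORES_FOR_PERCENTILE:
        raise ValueError(
            f"need at least {MIN_SCORES_FOR_PERCENTILE} scores for a "
            "meaningful percentile threshold"
        )
    pool = scores[scores > 0] if percentile_over == "nonzero" else scores
    if len(pool) == 0:
        pool = scores
    if percentile <= 0:
        threshold = float(pool.min())
    else:
        threshold = float(np.quantile(pool, percentile / 100.0, method="higher"))
    return scores >= threshold, threshold


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

@dataclass
class EvalReport:
    accuracy: float  # percent
    sensitivity: float
    specificity: float
    confusion: dict  # tp / tn / fp / fn
    folds: list = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": self.confusion,
            "folds": self.folds,
        }


@dataclass
class RiskModel:
    estimator: object
    columns: list
    params: RiskParams
    threshold: float  # heuristic score threshold learned from training data
    train_indices: np.ndarray = None
    test_indices: np.ndarray = None
    oversampled_from: np.ndarray = None  # provenance of duplicated rows

    def save(self, path: str | Path):
        joblib.dump({"estimator": self.estimator, "columns": self.columns,
                     "params": self.params.model_dump(),
                     "threshold": self.threshold}, path)

    @classmethod
    def load(cls, path: str | Path) -> "RiskModel":
        blob = joblib.load(path)
        return cls(estimator=blob["estimator"], columns=blob["columns"],
                   params=RiskParams(**blob["params"]),
                   threshold=blob["threshold"])


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float, dict]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = 100.0 * (tp + tn) / max(tp + tn + fp + fn, 1)
    sens = 100.0 * tp / max(tp + fn, 1)
    spec = 100.0 * tn / max(tn + fp, 1)
    return acc, sens, spec, {"tp": tp, "tn": tn, "fp": fp, "fn": fn}


def _oversample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Duplicate minority rows (with replacement) to class parity.

    Returns the augmented arrays and the source indices of the duplicates.
    """
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0 or n_pos == n_neg:
        return X, y, np.array([], dtype=int)
    minority = 1 if n_pos < n_neg else 0
    idx = np.flatnonzero(y == minority)
    extra = rng.choice(idx, size=abs(n_neg - n_pos), replace=True)
    return (np.vstack([X, X[extra]]), np.concatenate([y, y[extra]]), extra)


def _make_estimator(params: RiskParams):
    if params.classifier == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=params.seed)
    return LogisticRegression(max_iter=1000, random_state=params.seed)


def train_classifier(
    matrix: np.ndarray,
    labels: np.ndarray,
    params: RiskParams | None = None,
    threshold: float = float("nan"),
) -> tuple[RiskModel, EvalReport]:
    """Train a classifier to reproduce the heuristic high-risk labels.

    Stratified 60/40 split (seeded); minority-class oversampling by random
    duplication in the training split only; stratified K-fold CV metrics on
    the training data; final metrics on the untouched held-out 40%.
    """
    params = params or RiskParams()
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            "training data contains a single class; raise diverter behavior "
            "rates (or lower the percentile) so both risk classes appear"
        )
    indices = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        indices,
        train_size=params.train_fraction,
        stratify=y,
        shuffle=True,
        random_state=params.seed,
    )
    rng = np.random.default_rng(params.seed)

    folds = []
    n_splits = min(params.k_folds, int(np.bincount(y[train_idx]).min()))
    if n_splits >= 2:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=params.seed)
        for k, (tr, va) in enumerate(skf.split(X[train_idx], y[train_idx])):
            Xt, yt = X[train_idx][tr], y[train_idx][tr]
            if params.oversample:
                Xt, yt, _ = _oversample(Xt, yt, rng)
            est = clone(_make_estimator(params))
            est.fit(Xt, yt)
            pred = est.predict(X[train_idx][va])
            acc, sens, spec, conf = _metrics(y[train_idx][va], pred)
            folds.append({"fold": k, "accuracy": acc, "sensitivity": sens,
                          "specificity": spec, "confusion": conf})

    Xt, yt = X[train_idx], y[train_idx]
    oversampled_from = np.array([], dtype=int)
    if params.oversample:
        Xt, yt, extra = _oversample(Xt, yt, rng)
        oversampled_from = train_idx[extra]
    estimator = _make_estimator(params)
    estimator.fit(Xt, yt)

    pred = estimator.predict(X[test_idx])
    acc, sens, spec, conf = _metrics(y[test_idx], pred)
    report = EvalReport(accuracy=acc, sensitivity=sens, specificity=spec,
                        confusion=conf, folds=folds)
    model = RiskModel(estimator=estimator, columns=list(FEATURE_ORDER),
                      params=params, threshold=threshold,
                      train_indices=train_idx, test_indices=test_idx,
                      oversampled_from=oversampled_from)
    return model, report


def classify_stream(
    model: RiskModel,
    features: pd.DataFrame,
    timestamps: pd.Series | None = None,
) -> pd.DataFrame:
    """Score and classify every transaction; one assessment per row.

    Output columns: ``txn_id``, ``clinician``, ``score`` (heuristic weighted
    score), ``heuristic_label``, ``predicted_label``,
    ``predicted_probability`` and ``alert_timestamp`` (the transaction
    timestamp for predicted-high rows, NaT otherwise) — emulating a daily
    feed in which each day's transactions are scored as they arrive.
    """
    missing = [c for c in model.columns if c not in features.columns]
    if missing:
        raise ValueError(f"feature columns missing from input: {missing}")
    X = features[model.columns].to_numpy(dtype=float)
    scores = score(features, model.params.weights)
    proba = model.estimator.predict_proba(X)[:, list(model.estimator.classes_).index(1)]
    pred = model.estimator.predict(X).astype(int)
    if timestamps is None and "timestamp" in features.columns:
        timestamps = features["timestamp"]
    ts = (pd.to_datetime(timestamps).reset_index(drop=True)
          if timestamps is not None else pd.Series(pd.NaT, index=range(len(X))))
    heuristic = (
        scores >= model.threshold
        if np.isfinite(model.threshold)
        else np.zeros(len(X), dtype=bool)
    )
    out = pd.DataFrame({
        "txn_id": features["txn_id"].to_numpy(),
        "clinician": features["clinician"].to_numpy(),
        "score": scores,
        "heuristic_label": np.where(heuristic, "high", "low"),
        "predicted_label": np.where(pred == 1, "high", "low"),
        "predicted_probability": proba,
        "alert_timestamp": ts.where(pd.Series(pred == 1)),
    })
    return out


def run_risk_pipeline(
    features: pd.DataFrame,
    params: RiskParams | None = None,
) -> tuple[RiskModel, EvalReport, pd.DataFrame]:
    """Score -> percentile-label -> train -> classify, in one call."""
    params = params or RiskParams()
    scores = score(features, params.weights)
    labels, threshold = label_high_risk(scores, params.percentile,
                                        params.percentile_over)
    matrix = features[FEATURE_ORDER].to_numpy(dtype=float)
    model, report = train_classifier(matrix, labels, params, threshold)
    assessments = classify_stream(model, features)
    return model, report, assessments
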