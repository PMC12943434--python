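"""Patient-grouped out-of-fold classification and patient-level metrics.

Repeated exposures of one patient are strongly correlated, so the
cross-validation is grouped by patient id: all frames of a patient land in
the same fold, and every frame receives exactly one out-of-fold predicted
probability from a model that never saw its patient.  Frame-level
probabilities are averaged per patient; ROC AUC, average precision and the
Youden operating point are reported at both levels.

The per-fold model is the standard stack for this kind of
high-dimensional, small-n imaging problem: per-feature standardization,
PCA projection (default 20 components), and a class-weighted L2 logistic
model (weights inversely proportional to training-fold class frequency).
A Random Forest variant is available behind the same contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import average_precision_score, roc_curve
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix

__all__ = [
    "FoldAssignment",
    "RocSummary",
    "grouped_stratified_folds",
    "oof_probabilities",
    "aggregate_to_patients",
    "roc_ap_metrics",
    "youden_point",
]

POSITIVE_LABEL = "cancer"


@dataclass
class FoldAssignment:
    """Patient-grouped fold assignment: one test-fold id per frame."""

    assignments: pd.DataFrame  # columns: frame_id, patient_id, label, fold
    k: int

    def __post_init__(self) -> None:
        per_patient = self.assignments.groupby("patient_id")["fold"].nunique()
        if (per_patient > 1).any():
            bad = per_patient[per_patient > 1].index.tolist()
            raise ValueError(f"patients split across folds: {bad}")


@dataclass
class RocSummary:
    """ROC curve with its scalar summaries."""

    auc: float
    ap: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    positive_label: str = POSITIVE_LABEL


def _require_metadata(metadata: pd.DataFrame) -> None:
    missing = {"frame_id", "patient_id", "label"} - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")


def grouped_stratified_folds(
    metadata: pd.DataFrame, k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Partition patients into k folds, approximately class-balanced.

    Stratification is by frame label with the patient id as the grouping
    variable, so each patient's frames stay together.  Deterministic for a
    given seed.
    """
    _require_metadata(metadata)
    n_patients = metadata["patient_id"].nunique()
    if k > n_patients:
        raise ValueError(f"k = {k} folds exceed the {n_patients} distinct patients")
    if metadata["label"].nunique() < 2:
        raise ValueError("both classes must be present to stratify folds")
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.full(len(metadata), -1, dtype=int)
    for fold_id, (_, test_idx) in enumerate(
        splitter.split(np.zeros(len(metadata)), metadata["label"], metadata["patient_id"])
    ):
        fold[test_idx] = fold_id
    out = metadata[["frame_id", "patient_id", "label"]].copy()
    out["fold"] = fold
    return FoldAssignment(assignments=out, k=k)


def _make_classifier(classifier: str, C: float, seed: int):
    if classifier == "logistic":
        return LogisticRegression(C=C, class_weight="balanced", max_iter=5000)
    if classifier == "random_forest":
        return RandomForestClassifier(
            n_estimators=400, class_weight="balanced", random_state=seed
        )
    raise ValueError(f"unknown classifier {classifier!r}")


def oof_probabilities(
    features: FeatureMatrix | np.ndarray,
    metadata: pd.DataFrame,
    folds: FoldAssignment,
    n_components: int = 20,
    positive_label: str = POSITIVE_LABEL,
    classifier: str = "logistic",
    C: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-fold predicted probability of the positive class per frame.

    For each fold the standardization, the PCA projection and the
    classifier are fit on the training rows only and applied to the
    held-out rows.  Returns a score table with columns ``frame_id``,
    ``patient_id``, ``label``, ``score``.
    """
    _require_metadata(metadata)
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.shape[0] != len(metadata):
        raise ValueError("feature rows and metadata rows do not align")
    if isinstance(features, FeatureMatrix) and features.frame_ids != list(metadata["frame_id"]):
        raise ValueError("feature matrix row order does not match metadata order")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    merged = metadata.merge(folds.assignments[["frame_id", "fold"]], on="frame_id")
    if merged["fold"].isna().any():
        raise ValueError("fold assignment does not cover every frame")
    y = (merged["label"] == positive_label).to_numpy()

    scores = np.full(len(merged), np.nan)
    for fold_id in sorted(merged["fold"].unique()):
        test = (merged["fold"] == fold_id).to_numpy()
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"training split of fold {fold_id} contains a single class")
        n_comp = min(n_components, int(train.sum()) - 1, X.shape[1])
        if n_comp < n_components:
            warnings.warn(
                f"fold {fold_id}: n_components capped at {n_comp} (training-fold rank)"
            )
        model = Pipeline(
            [
                ("scale", StandardScaler()),
                # whitened projection: unit-variance components, so the
                # downstream L2 logistic model is invariant to feature
                # duplication/rescaling absorbed by the projection
                ("project", PCA(n_components=n_comp, whiten=True, random_state=seed)),
                ("clf", _make_classifier(classifier, C, seed)),
            ]
        )
        model.fit(X[train], y[train])
        positive_col = list(model.classes_).index(True)
        scores[test] = model.predict_proba(X[test])[:, positive_col]

    out = merged[["frame_id", "patient_id", "label"]].copy()
    out["score"] = scores
    return out


def aggregate_to_patients(scores: pd.DataFrame, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Patient probability = arithmetic mean of that patient's frame scores."""
    table = scores
    if "patient_id" not in table.columns:
        if metadata is None:
            raise ValueError("need patient ids (in scores or via metadata)")
        table = table.merge(metadata[["frame_id", "patient_id", "label"]], on="frame_id")
    labels = table.groupby("patient_id")["label"].nunique()
    if (labels > 1).any():
        bad = labels[labels > 1].index.tolist()
        raise ValueError(f"patients with conflicting frame labels: {bad}")
    out = (
        table.groupby("patient_id")
        .agg(score=("score", "mean"), label=("label", "first"))
        .reset_index()
    )
    return out


def roc_ap_metrics(
    scores: pd.DataFrame, positive_label: str = POSITIVE_LABEL
) -> RocSummary:
    """ROC curve, trapezoidal AUC and average precision of a score table.

    Ties in the scores receive half-credit in the AUC (the rank-statistic
    definition); AP is the step sum over descending-score ranks.
    """
    y = (scores["label"] == positive_label).to_numpy()
    s = scores["score"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute ROC metrics")
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    return RocSummary(
        auc=float(_trapezoid_auc(fpr, tpr)),
        ap=float(average_precision_score(y, s)),
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        positive_label=positive_label,
    )


def youden_point(roc: RocSummary) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties are broken toward the higher threshold (fewer predicted
    positives).  Returns ``(threshold, sensitivity, specificity)``.
    """
    j = roc.tpr - roc.fpr
    best = int(np.argmax(j))  # thresholds are descending: first max = highest
    if j[best] <= 0:
        warnings.warn("scores are uninformative: Youden J = 0 at every threshold")
    return float(roc.thresholds[best]), float(roc.tpr[best]), float(1.0 - roc.fpr[best])
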