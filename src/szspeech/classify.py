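"""Cross-validated classification of responses into patient vs control.

Protocol: five evaluations, each a stratified five-fold cross-validation
of the response-level feature table with its own random seed; the same
seed list is reused across classifier families and feature sets so fold
assignments are shared.  Within each fold, undefined feature cells are
imputed with the training-fold mean and (for the linear SVM) features
are standardized with training-fold statistics — no test-fold leakage.
Fold predictions are pooled per evaluation; accuracy and the precision,
recall and F1 of the patient (positive) label are reported as mean (SD)
over the five evaluations, on the percent scale.

Classifiers: gradient-boosted trees (XGBoost), random forest, linear
SVM — all at library-default hyperparameters, the only reproducible
choice when none are published.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, StratifiedGroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

from .cohort import FeatureTable, feature_columns

log = logging.getLogger(__name__)

CLASSIFIER_FAMILIES = ("xgb", "rf", "svm")
METRIC_NAMES = ("accuracy", "precision", "recall", "f1")
POSITIVE_LABEL = "patient"


@dataclass(frozen=True)
class EvaluationProtocol:
    """Evaluation design: seeds, folds, classifier family, feature set."""

    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    n_folds: int = 5
    classifier: str = "xgb"
    feature_set: str = "combined"
    group_folds: bool = False  # speaker-disjoint folds (generalization variant)
    pool_folds: bool = True  # pool fold predictions per evaluation

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIER_FAMILIES:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not self.seeds:
            raise ValueError("at least one evaluation seed is required")

    @property
    def n_evaluations(self) -> int:
        return len(self.seeds)


@dataclass
class EvaluationResult:
    """Mean (SD) of each metric over evaluations, percent scale."""

    protocol: EvaluationProtocol
    per_evaluation: pd.DataFrame  # one row per seed, columns METRIC_NAMES

    def mean(self, metric: str) -> float:
        return float(self.per_evaluation[metric].mean())

    def sd(self, metric: str) -> float:
        return float(self.per_evaluation[metric].std(ddof=1))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.per_evaluation.mean(),
                "sd": self.per_evaluation.std(ddof=1),
            }
        )


def metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Accuracy and patient-label precision/recall/F1 from confusion counts.

    Percent scale.  A zero denominator (e.g. no predicted positives)
    yields 0 for that metric, with a warning, so aggregation stays total.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("no predictions to score")
    accuracy = 100.0 * (tp + tn) / total
    precision = _safe_ratio(tp, tp + fp, "precision")
    recall = _safe_ratio(tp, tp + fn, "recall")
    if precision + recall == 0.0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def _safe_ratio(num: int, denom: int, name: str) -> float:
    if denom == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0", UserWarning)
        return 0.0
    return 100.0 * num / denom


def _make_classifier(family: str, seed: int):
    if family == "xgb":
        return XGBClassifier(random_state=seed, verbosity=0)
    if family == "rf":
        return RandomForestClassifier(random_state=seed)
    if family == "svm":
        return LinearSVC(random_state=seed)
    raise ValueError(f"unknown classifier {family!r}")


def _impute_train_mean(X_train: np.ndarray, X_test: np.ndarray):
    """Fill NaN cells with the training-fold column mean in both partitions."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(X_train, axis=0)
    means = np.where(np.isnan(means), 0.0, means)  # column undefined everywhere
    X_train = np.where(np.isnan(X_train), means, X_train)
    X_test = np.where(np.isnan(X_test), means, X_test)
    return X_train, X_test


def fold_assignments(
    y: np.ndarray,
    seed: int,
    n_folds: int,
    groups: Optional[np.ndarray] = None,
) -> list[np.ndarray]:
    """Test-index arrays of the stratified folds for one evaluation seed.

    Depends only on (y, seed, n_folds[, groups]) — not on the feature set
    or classifier family — so folds are shared across both, as the
    protocol requires.
    """
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros_like(y), y, groups)]
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros_like(y), y)]


def run_cv(table: FeatureTable, protocol: EvaluationProtocol) -> EvaluationResult:
    """Run the multi-seed stratified cross-validation protocol.

    Returns per-evaluation pooled metrics (or fold-averaged metrics when
    ``protocol.pool_folds`` is False) for the configured classifier
    family and feature set.
    """
    X = table.features(protocol.feature_set).to_numpy(dtype=float)
    y = (table.labels == POSITIVE_LABEL).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both group labels must be present")
    groups = (
        table.df["participant_id"].to_numpy() if protocol.group_folds else None
    )
    return _run_cv_matrix(X, y, groups, protocol)


def _run_cv_matrix(
    X: np.ndarray,
    y: np.ndarray,
    groups: Optional[np.ndarray],
    protocol: EvaluationProtocol,
) -> EvaluationResult:
    rows = []
    for seed in protocol.seeds:
        folds = fold_assignments(y, seed, protocol.n_folds, groups)
        fold_metrics = []
        pooled_pred = np.empty_like(y)
        for test_idx in folds:
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_idx] = False
            X_train, X_test = _impute_train_mean(X[train_mask], X[test_idx])
            if protocol.classifier == "svm":
                scaler = StandardScaler().fit(X_train)
                X_train = scaler.transform(X_train)
                X_test = scaler.transform(X_test)
            clf = _make_classifier(protocol.classifier, seed)
            clf.fit(X_train, y[train_mask])
            pred = np.asarray(clf.predict(X_test), dtype=int)
            pooled_pred[test_idx] = pred
            if not protocol.pool_folds:
                fold_metrics.append(_metrics_from_arrays(y[test_idx], pred))
        if protocol.pool_folds:
            rows.append(_metrics_from_arrays(y, pooled_pred))
        else:
            rows.append(
                {m: float(np.mean([fm[m] for fm in fold_metrics])) for m in METRIC_NAMES}
            )
    per_evaluation = pd.DataFrame(rows, index=list(protocol.seeds))
    return EvaluationResult(protocol=protocol, per_evaluation=per_evaluation)


def _metrics_from_arrays(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return metrics(tp, fp, fn, tn)


@dataclass
class AblationResult:
    """Combined-model F1 with each feature removed, against the baseline."""

    baseline_f1: float
    baseline_sd: float
    per_feature: pd.DataFrame  # index: removed feature; columns f1_mean, f1_sd


def ablate(table: FeatureTable, protocol: EvaluationProtocol) -> AblationResult:
    """Leave-one-feature-out ablation over the combined feature set.

    Reruns the full protocol once per removed feature with the same
    seeds; reports the F1 mean (SD) over evaluations for each removal and
    for the all-features baseline.
    """
    if protocol.feature_set != "combined":
        raise ValueError("ablation is defined over the combined feature set")
    baseline = run_cv(table, protocol)
    cols = list(feature_columns("combined"))
    y = (table.labels == POSITIVE_LABEL).to_numpy(dtype=int)
    groups = table.df["participant_id"].to_numpy() if protocol.group_folds else None
    rows = {}
    for feat in cols:
        X = table.df[[c for c in cols if c != feat]].to_numpy(dtype=float)
        result = _run_cv_matrix(X, y, groups, protocol)
        rows[feat] = {"f1_mean": result.mean("f1"), "f1_sd": result.sd("f1")}
        log.info("ablation: removed %-14s F1 %.1f", feat, rows[feat]["f1_mean"])
    return AblationResult(
        baseline_f1=baseline.mean("f1"),
        baseline_sd=baseline.sd("f1"),
        per_feature=pd.DataFrame.from_dict(rows, orient="index"),
    )


def plot_ablation(result: AblationResult, path) -> "Path":
    """Bar chart of F1 per removed feature with the baseline as a line."""
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    per = result.per_feature
    fig, ax = plt.subplots(figsize=(0.5 * len(per) + 2, 4))
    ax.bar(per.index, per["f1_mean"], yerr=per["f1_sd"], color="#4878a8")
    ax.axhline(result.baseline_f1, color="red", label=f"all features ({result.baseline_f1:.1f})")
    ax.set_ylabel("F1 (patient label, %)")
    ax.set_xlabel("removed feature")
    ax.tick_params(axis="x", rotation=90)
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
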