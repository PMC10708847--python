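"""Pass/fail discrimination from beta features with a small MLP.

Each subject contributes a five-value feature vector — the mean accepted
beta power within each of the four video segments plus the session total
mean — standardized across the cohort.  A multilayer perceptron is
validated with leave-one-out cross-validation: in every iteration one
subject is held out, a grid search (inner stratified k-fold on the
training subjects only) picks the hyperparameters, the model is refit on
all training subjects, and the held-out probability is recorded.  Pooled
predictions yield the ROC curve, AUC and confusion-matrix metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .core import SessionAnnotation, SingleClassError
from .dsp import ProcessingConfig, SubjectSummary, segment_mean_betas

__all__ = [
    "DEFAULT_GRID",
    "FeatureTable",
    "ClassifierReport",
    "build_features",
    "loocv_predict",
    "evaluate",
    "confusion_metrics",
]

# the platform documents only "grid search"; this grid spans small
# architectures appropriate for tens of subjects and five features
DEFAULT_GRID: dict[str, list] = {
    "hidden_layer_sizes": [(4,), (8,), (8, 4)],
    "alpha": [1e-4, 1e-3, 1e-2],
    "learning_rate_init": [1e-3, 1e-2],
}

POSITIVE_LABEL = 1  # "pass"


@dataclass
class FeatureTable:
    """Cohort-standardized classifier inputs with pass/fail labels."""

    subject_ids: list[str]
    X: np.ndarray  # (n_subjects, n_features)
    y: np.ndarray  # 1 = pass (score >= pass mark), 0 = fail
    feature_names: list[str]

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class ClassifierReport:
    """Pooled LOOCV evaluation: confusion matrix, metrics, ROC/AUC."""

    probabilities: np.ndarray
    labels: np.ndarray
    threshold: float
    confusion: tuple[int, int, int, int]  # TP, FP, FN, TN; positive = pass
    recall: float
    precision: float
    accuracy: float
    f1: float
    roc_points: np.ndarray  # columns: fpr, tpr
    auc: float
    chosen_hyperparams: list[dict] = field(default_factory=list)

    def rounded(self, ndigits: int = 2) -> dict:
        return {
            "recall": round(self.recall, ndigits),
            "precision": round(self.precision, ndigits),
            "accuracy": round(self.accuracy, ndigits),
            "f1": round(self.f1, ndigits),
            "auc": round(self.auc, ndigits),
        }


def build_features(
    summaries: list[SubjectSummary],
    annotation: SessionAnnotation,
    scores,
    pass_mark: float = 5.0,
    cfg: ProcessingConfig = ProcessingConfig(),
    total_only: bool = False,
) -> FeatureTable:
    """Assemble the standardized per-subject feature matrix.

    By default features are the per-video-segment mean beta powers plus
    the session total mean (z-scored column-wise across the cohort);
    ``total_only`` keeps just the total for a one-feature variant.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(summaries):
        raise ValueError("scores and summaries must be parallel")
    seg_names = [f"video{i + 1}_mean_beta" for i in range(len(annotation.video_segments))]
    rows = []
    for s in summaries:
        seg = segment_mean_betas(s, annotation, cfg)
        rows.append(np.concatenate([seg, [s.total_mean_beta]]))
    X = np.asarray(rows, dtype=float)
    names = seg_names + ["total_mean_beta"]
    if total_only:
        X = X[:, -1:]
        names = names[-1:]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    y = (scores >= pass_mark).astype(int)
    return FeatureTable(
        subject_ids=[s.subject_id for s in summaries],
        X=X,
        y=y,
        feature_names=names,
    )


def loocv_predict(
    features: FeatureTable,
    grid: dict | None = None,
    seed: int = 0,
    inner_folds: int = 5,
    max_iter: int = 300,
) -> tuple[np.ndarray, list[dict]]:
    """Leave-one-out predicted pass probabilities with nested grid search.

    Hyperparameters are re-selected inside every training fold so the
    held-out subject never influences its own model.  Returns the pooled
    probability vector (one entry per subject, in input order) and the
    per-fold chosen hyperparameters.
    """
    X, y = features.X, features.y
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects for leave-one-out")
    if len(np.unique(y)) < 2:
        raise SingleClassError("both pass and fail labels must be present")
    grid = grid or DEFAULT_GRID
    probs = np.empty(n)
    chosen: list[dict] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i in range(n):
            train = np.delete(np.arange(n), i)
            ytr = y[train]
            if len(np.unique(ytr)) < 2:
                raise SingleClassError(f"training fold {i} lost one class")
            k = min(inner_folds, int(np.bincount(ytr).min()))
            base = MLPClassifier(max_iter=max_iter, random_state=seed)
            if k >= 2 and _grid_size(grid) > 1:
                cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
                search = GridSearchCV(base, grid, cv=cv, scoring="accuracy", n_jobs=None)
                search.fit(X[train], ytr)
                model = search.best_estimator_
                chosen.append(dict(search.best_params_))
            else:
                params = {k_: v[0] for k_, v in grid.items()}
                model = base.set_params(**params).fit(X[train], ytr)
                chosen.append(params)
            pos = list(model.classes_).index(POSITIVE_LABEL)
            probs[i] = model.predict_proba(X[i:i + 1])[0, pos]
    return probs, chosen


def _grid_size(grid: dict) -> int:
    size = 1
    for v in grid.values():
        size *= len(v)
    return size


def evaluate(probabilities, labels, threshold: float = 0.5,
             chosen_hyperparams: list[dict] | None = None) -> ClassifierReport:
    """Confusion-matrix metrics and ROC/AUC from pooled predictions.

    Hard labels are probability >= threshold; "pass" is the positive
    class.  The ROC curve sweeps every distinct probability cut-point and
    the AUC is the trapezoid integral.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must be parallel vectors")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    n = len(y)
    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    accuracy = (tp + tn) / n
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else float("nan"))
    if len(np.unique(y)) == 2:
        fpr, tpr, _ = roc_curve(y, p, pos_label=POSITIVE_LABEL)
        roc = np.column_stack([fpr, tpr])
        area = float(_trapezoid_auc(fpr, tpr))
    else:
        roc = np.empty((0, 2))
        area = float("nan")
    return ClassifierReport(
        probabilities=p,
        labels=y,
        threshold=threshold,
        confusion=(tp, fp, fn, tn),
        recall=recall,
        precision=precision,
        accuracy=accuracy,
        f1=f1,
        roc_points=roc,
        auc=area,
        chosen_hyperparams=chosen_hyperparams or [],
    )


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Metrics straight from a tabulated confusion matrix (worked examples)."""
    n = tp + fp + fn + tn
    recall = tp / (tp + fn)
    precision = tp / (tp + fp)
    accuracy = (tp + tn) / n
    f1 = 2 * precision * recall / (precision + recall)
    return {"recall": recall, "precision": precision, "accuracy": accuracy, "f1": f1}
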