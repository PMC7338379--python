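"""Train/test protocol: 80/20 split, five-fold CV, per-class metrics.

The evaluation protocol holds out a stratified 20% test set first, then
partitions the remaining 80% training pool into five stratified folds. One
fresh classifier is trained per fold (augmentation on the training portion
only), per-epoch train/validation accuracy curves are recorded and averaged
across folds, and the best fold model — highest final validation accuracy,
ties broken by lowest fold index — is evaluated once on the untouched test
set. Per-class precision, recall and F1 (harmonic mean,
``F1 = 2 p r / (p + r)``) are computed from the 3x3 confusion matrix at
argmax prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split

__all__ = ["SplitPlan", "Splits", "MetricsReport", "make_splits", "train_cv", "evaluate", "CVResult"]


@dataclass(frozen=True)
class SplitPlan:
    """Hold-out fraction, fold count and stratification policy."""

    test_fraction: float = 0.20
    n_folds: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("cross-validation needs n_folds >= 2")


@dataclass(frozen=True)
class Splits:
    """Index-based partition: disjoint test set plus (train, val) fold pairs.

    Fold validation sets are pairwise disjoint and union to the training
    pool; every index set refers to positions in the original manifest.
    """

    test_idx: np.ndarray
    folds: tuple[tuple[np.ndarray, np.ndarray], ...]

    @property
    def train_pool_idx(self) -> np.ndarray:
        return np.sort(np.concatenate([val for _, val in self.folds]))


def make_splits(labels: Sequence, plan: SplitPlan = SplitPlan()) -> Splits:
    """Partition a labelled manifest per the hold-out + k-fold protocol.

    ``labels`` is the per-item class label column (anything array-like);
    items labelled ``unlabeled`` are rejected — they carry no supervision.
    """
    y = np.asarray(labels)
    if np.any(y == "unlabeled"):
        raise ValueError("manifest contains 'unlabeled' items; filter them first")
    n = len(y)
    if n < 2 * plan.n_folds:
        raise ValueError(f"too few items ({n}) for {plan.n_folds}-fold CV")
    if plan.stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < plan.n_folds:
            raise ValueError(
                "stratified folds need at least n_folds labelled items per class"
            )
    idx = np.arange(n)
    strat = y if plan.stratified else None
    pool_idx, test_idx = train_test_split(
        idx, test_size=plan.test_fraction, stratify=strat, random_state=plan.seed
    )
    cv_cls = StratifiedKFold if plan.stratified else KFold
    kf = cv_cls(n_splits=plan.n_folds, shuffle=True, random_state=plan.seed)
    folds = tuple(
        (pool_idx[tr], pool_idx[va]) for tr, va in kf.split(pool_idx, y[pool_idx])
    )
    return Splits(test_idx=np.sort(test_idx), folds=folds)


@dataclass
class CVResult:
    """Per-fold curves, their across-fold averages, and the selected model."""

    fold_histories: list[dict]
    acc_avg: np.ndarray  # per-epoch training accuracy, averaged over folds
    val_acc_avg: np.ndarray  # per-epoch validation accuracy, averaged
    best_fold: int
    best_model: object

    def curves_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.acc_avg) + 1),
                "acc_avg": self.acc_avg,
                "val_acc_avg": self.val_acc_avg,
            }
        )


def train_cv(
    X: np.ndarray,
    y: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    estimator,
) -> CVResult:
    """Train one fresh clone of ``estimator`` per (train, val) fold.

    Records per-epoch train/validation accuracy for every fold, averages the
    curves, and selects the model with the highest final-epoch validation
    accuracy (lowest fold index on ties).
    """
    if len(folds) == 0:
        raise ValueError("no folds supplied")
    y = np.asarray(y)
    histories, models = [], []
    for k, (tr, va) in enumerate(folds):
        if len(tr) == 0 or len(va) == 0:
            raise ValueError(f"fold {k} is empty")
        est = clone(estimator)
        if hasattr(est, "random_state"):
            est.set_params(random_state=int(getattr(est, "random_state", 0)) + k)
        est.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
        histories.append(est.history_)
        models.append(est)
    acc_avg = np.mean([h["acc"] for h in histories], axis=0)
    val_acc_avg = np.mean([h["val_acc"] for h in histories], axis=0)
    finals = np.array([h["val_acc"][-1] for h in histories])
    best_fold = int(np.argmax(finals))  # argmax takes the first max: lowest index
    return CVResult(
        fold_histories=histories,
        acc_avg=acc_avg,
        val_acc_avg=val_acc_avg,
        best_fold=best_fold,
        best_model=models[best_fold],
    )


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1 and the confusion matrix behind them."""

    classes: tuple
    confusion: np.ndarray  # (k, k) counts; rows = true, cols = predicted
    precision: dict
    recall: dict
    f1: dict
    accuracy: float
    curves: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion_matrix": self.confusion.tolist(),
            "precision": {k: float(v) for k, v in self.precision.items()},
            "recall": {k: float(v) for k, v in self.recall.items()},
            "f1": {k: float(v) for k, v in self.f1.items()},
            "accuracy": float(self.accuracy),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=list(self.classes), columns=list(self.classes))


def metrics_from_confusion(confusion: np.ndarray, classes: Sequence) -> MetricsReport:
    """Per-class precision/recall/F1 directly from a confusion matrix."""
    confusion = np.asarray(confusion, dtype=int)
    k = confusion.shape[0]
    if confusion.shape != (k, k) or k != len(classes):
        raise ValueError("confusion matrix shape does not match classes")
    tp = np.diag(confusion).astype(float)
    pred_tot = confusion.sum(axis=0).astype(float)
    true_tot = confusion.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        r = np.where(true_tot > 0, tp / true_tot, 0.0)
        f1 = np.where(p + r > 0, 2 * p * r / (p + r), 0.0)
    total = confusion.sum()
    acc = float(tp.sum() / total) if total else 0.0
    cls = tuple(classes)
    return MetricsReport(
        classes=cls,
        confusion=confusion,
        precision=dict(zip(cls, p)),
        recall=dict(zip(cls, r)),
        f1=dict(zip(cls, f1)),
        accuracy=acc,
    )


def evaluate(model, X_test: np.ndarray, y_test: Sequence) -> MetricsReport:
    """Confusion matrix at argmax prediction plus per-class P/R/F1.

    ``y_test`` must be fully labelled; the class axis follows the model's
    ``classes_`` ordering. Cross-checked in the test suite against both a
    brute-force oracle and scikit-learn's reference metrics.
    """
    y_test = np.asarray(y_test)
    if np.any(y_test == "unlabeled"):
        raise ValueError("test set contains unlabeled items")
    if len(y_test) == 0:
        raise ValueError("empty test set")
    classes = tuple(model.classes_)
    y_pred = model.predict(X_test)
    cm = confusion_matrix(y_test, y_pred, labels=list(classes))
    report = metrics_from_confusion(cm, classes)
    # consistency with the library reference (cheap internal audit)
    p, r, f1, _ = precision_recall_fscore_support(
        y_test, y_pred, labels=list(classes), zero_division=0
    )
    assert np.allclose(list(report.precision.values()), p)
    assert np.allclose(list(report.recall.values()), r)
    assert np.allclose(list(report.f1.values()), f1)
    return report
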