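"""Data segmentation and the metric suite.

The evaluation protocol holds out 20% of the clips as a final test set, then
cycles the remaining 80% through 5-fold cross-validation; each metric is
reported per fold together with the cross-fold mean and sample standard
deviation.  Splits are stratified by species and *grouped* by source clip,
so a time-reversed copy can never land on the other side of a split from the
clip it was derived from.

The headline accuracy is the mean over classes of the one-vs-rest binary
accuracy (TP+TN)/(TP+TN+FP+FN) — for an N-class problem this equals
(N-2)/N + 2/N * plain accuracy, so it is never below the plain multiclass
accuracy.  Both are reported.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedGroupKFold

from .audio_io import ManifestRecord
from .augment import FLIP_SUFFIX

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "ConfusionMatrix",
    "MetricsReport",
    "make_split",
    "confusion",
    "accuracy_eq6",
    "plain_accuracy",
    "f1_score",
    "prf1",
    "aggregate_folds",
    "group_key",
]


# ---------------------------------------------------------------------------
# splitting


@dataclass(frozen=True)
class SplitPlan:
    test_idx: np.ndarray
    folds: tuple[tuple[np.ndarray, np.ndarray], ...]  # (train_idx, val_idx) per fold
    seed: int
    stratified: bool = True

    @property
    def k(self) -> int:
        return len(self.folds)


def group_key(record: ManifestRecord) -> str:
    """Key tying a flipped clip to its source (same stem without the suffix)."""
    stem = Path(record.path).stem
    if stem.endswith(FLIP_SUFFIX):
        stem = stem[: -len(FLIP_SUFFIX)]
    return f"{record.label}/{stem}"


def make_split(
    manifest: Sequence[ManifestRecord],
    k: int = 5,
    test_frac: float = 0.20,
    seed: int = 0,
) -> SplitPlan:
    """Holdout + k-fold split plan over manifest indices.

    ``test_frac`` of the data is cut out first (never used for folds); the
    remainder is partitioned into ``k`` validation folds.  Stratified by
    label, grouped by source clip, deterministic given ``seed``.
    """
    labels = np.array([r.label for r in manifest])
    groups = np.array([group_key(r) for r in manifest])
    counts = Counter(labels)
    for label, n in counts.items():
        if n < k:
            raise ValueError(f"class {label!r} has only {n} samples; need at least k={k}")
    n_test_splits = int(round(1.0 / test_frac))
    if abs(1.0 / n_test_splits - test_frac) > 1e-9:
        raise ValueError(f"test_frac must be 1/int for grouped stratified splitting, got {test_frac}")
    outer = StratifiedGroupKFold(n_splits=n_test_splits, shuffle=True, random_state=seed)
    rest_idx, test_idx = next(outer.split(np.zeros(len(labels)), labels, groups))
    inner = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed + 1)
    folds = tuple(
        (rest_idx[tr], rest_idx[va])
        for tr, va in inner.split(np.zeros(len(rest_idx)), labels[rest_idx], groups[rest_idx])
    )
    return SplitPlan(test_idx=test_idx, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# confusion matrix


@dataclass(frozen=True)
class ConfusionMatrix:
    """Count matrix with rows = true class, columns = predicted class."""

    matrix: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int64)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] == 0:
            raise ValueError(f"confusion matrix must be square and non-empty, got {m.shape}")
        if np.any(m < 0):
            raise ValueError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    # one-vs-rest decompositions
    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def fn(self) -> np.ndarray:
        return self.matrix.sum(axis=1) - self.tp

    @property
    def fp(self) -> np.ndarray:
        return self.matrix.sum(axis=0) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.total - self.tp - self.fn - self.fp


def confusion(y_true, y_pred, n_classes: int | None = None, labels: Sequence[str] | None = None) -> ConfusionMatrix:
    """Tally integer predictions against integer truth."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    if y_true.min() < 0 or max(y_true.max(), y_pred.max()) >= n_classes:
        raise ValueError("labels out of range")
    m = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    return ConfusionMatrix(matrix=m, labels=tuple(labels) if labels else None)


# ---------------------------------------------------------------------------
# metrics


def accuracy_eq6(cm: ConfusionMatrix) -> float:
    """Mean over classes of one-vs-rest binary accuracy, in percent."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class = (cm.tp + cm.tn) / cm.total
    return float(per_class.mean() * 100.0)


def plain_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples, in percent."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.matrix) / cm.total * 100.0)


def f1_score(precision, recall):
    """Harmonic mean of precision and recall (any matching units)."""
    precision = np.asarray(precision, dtype=np.float64)
    recall = np.asarray(recall, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(precision + recall > 0, 2.0 * precision * recall / (precision + recall), np.nan)
    return float(out) if out.ndim == 0 else out


def prf1(cm: ConfusionMatrix) -> dict[str, np.ndarray]:
    """Per-class precision, recall and F1 in percent (one-vs-rest).

    Classes with a zero denominator get NaN with a warning rather than an
    arbitrary fill value.
    """
    tp, fp, fn = cm.tp.astype(float), cm.fp.astype(float), cm.fn.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        recall = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        f1 = f1_score(precision, recall)
    for name, arr in (("precision", precision), ("recall", recall), ("f1", f1)):
        bad = np.flatnonzero(np.isnan(arr))
        if bad.size:
            warnings.warn(f"{name} undefined for class index(es) {bad.tolist()}", RuntimeWarning, stacklevel=2)
    return {"precision": precision * 100.0, "recall": recall * 100.0, "f1": f1 * 100.0}


@dataclass
class MetricsReport:
    """Metrics for one evaluation (one fold, or the holdout test set)."""

    cm: ConfusionMatrix
    accuracy_eq6: float = field(init=False)
    plain_accuracy: float = field(init=False)
    per_class: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        self.accuracy_eq6 = accuracy_eq6(self.cm)
        self.plain_accuracy = plain_accuracy(self.cm)
        self.per_class = prf1(self.cm)

    def to_dict(self) -> dict:
        out = {
            "accuracy_eq6": round(self.accuracy_eq6, 2),
            "plain_accuracy": round(self.plain_accuracy, 2),
            "confusion": self.cm.matrix.tolist(),
        }
        names = self.cm.labels or tuple(str(i) for i in range(self.cm.n_classes))
        for metric, values in self.per_class.items():
            out[metric] = {n: (None if np.isnan(v) else round(float(v), 2)) for n, v in zip(names, values)}
        return out


def aggregate_folds(values: Sequence[float]) -> dict[str, float]:
    """Cross-fold mean and sample (n-1) standard deviation of a metric."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least two folds to aggregate")
    return {"mean": float(values.mean()), "std": float(values.std(ddof=1))}
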