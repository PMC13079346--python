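"""Classification and segmentation metrics plus stability summaries.

Classification metrics follow the one-vs-rest confusion-count formulation:
accuracy, micro/macro/weighted precision-recall-F1.  Segmentation uses Dice
(2|P∩G|/(|P|+|G|)) and IoU (|P∩G|/|P∪G|) per class.  Stability across a
sweep is summarized by the arithmetic mean and the population standard
deviation (divide by n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "StabilitySummary",
    "confusion",
    "classification_report",
    "dice_iou",
    "multiclass_dice_iou",
    "stability",
    "MetricsReport",
]


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest counts derived from a K x K confusion matrix."""

    K: int
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    matrix: np.ndarray

    @property
    def n_per_class(self) -> np.ndarray:
        return self.tp + self.fn

    @property
    def n_total(self) -> int:
        return int(self.matrix.sum())


@dataclass
class StabilitySummary:
    values: list[float]
    mean: float
    std: float  # population (divide by n)


@dataclass
class MetricsReport:
    """Serializable bundle of evaluation results."""

    accuracy: float = float("nan")
    precision: float = float("nan")
    recall: float = float("nan")
    f1_micro: float = float("nan")
    f1_macro: float = float("nan")
    f1_weighted: float = float("nan")
    per_class_f1: list[float] = field(default_factory=list)
    per_class_dice: list[float] = field(default_factory=list)
    per_class_iou: list[float] = field(default_factory=list)
    mean_dice: float = float("nan")
    mean_iou: float = float("nan")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def confusion(labels_true: Sequence[int], labels_pred: Sequence[int],
              K: int) -> ConfusionCounts:
    """Confusion counts for labels in [0, K)."""
    t = np.asarray(labels_true, dtype=np.int64)
    p = np.asarray(labels_pred, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("length mismatch between true and predicted labels")
    if t.size and (min(t.min(), p.min()) < 0 or max(t.max(), p.max()) >= K):
        raise ValueError("labels out of range [0, K)")
    matrix = np.zeros((K, K), dtype=np.int64)
    np.add.at(matrix, (t, p), 1)
    tp = np.diag(matrix).astype(np.int64)
    fn = matrix.sum(axis=1) - tp
    fp = matrix.sum(axis=0) - tp
    tn = matrix.sum() - tp - fn - fp
    return ConfusionCounts(K=K, tp=tp, fp=fp, fn=fn, tn=tn, matrix=matrix)


def _safe_div(num, den, what: str):
    num, den = np.broadcast_arrays(
        np.asarray(num, dtype=np.float64), np.asarray(den, dtype=np.float64)
    )
    out = np.zeros(den.shape)
    nz = den != 0
    if not np.all(nz):
        warnings.warn(f"zero denominator in {what}; contributing 0", stacklevel=3)
    out[nz] = num[nz] / den[nz]
    return out if out.ndim else float(out)


def classification_report(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, micro precision/recall, and micro/macro/weighted F1."""
    n = counts.n_total
    if n == 0:
        raise ValueError("no samples")
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    nk = counts.n_per_class
    accuracy = tp.sum() / n
    precision = float(_safe_div(tp.sum(), (tp + fp).sum(), "precision"))
    recall = float(_safe_div(tp.sum(), (tp + fn).sum(), "recall"))
    f1_micro = float(
        _safe_div(2 * tp.sum(), 2 * tp.sum() + fp.sum() + fn.sum(), "micro F1")
    )
    per_class = _safe_div(2 * tp, 2 * tp + fp + fn, "per-class F1")
    f1_macro = float(per_class.mean())
    f1_weighted = float((nk / n * per_class).sum())
    return MetricsReport(
        accuracy=float(accuracy),
        precision=precision,
        recall=recall,
        f1_micro=f1_micro,
        f1_macro=f1_macro,
        f1_weighted=f1_weighted,
        per_class_f1=[float(v) for v in per_class],
    )


def dice_iou(pred_mask: np.ndarray, true_mask: np.ndarray
             ) -> tuple[float, float]:
    """Binary Dice and IoU; both defined as 1.0 when P = G = empty."""
    p = np.asarray(pred_mask).astype(bool)
    g = np.asarray(true_mask).astype(bool)
    if p.shape != g.shape:
        raise ValueError("mask shape mismatch")
    inter = np.logical_and(p, g).sum()
    psum, gsum = p.sum(), g.sum()
    if psum + gsum == 0:
        return 1.0, 1.0
    dice = 2.0 * inter / (psum + gsum)
    union = psum + gsum - inter
    iou = inter / union
    return float(dice), float(iou)


def multiclass_dice_iou(pred_labels: np.ndarray, true_labels: np.ndarray,
                        K: int, include_background: bool = False
                        ) -> MetricsReport:
    """Per-class one-vs-rest Dice/IoU and their mean.

    The mean excludes the background class (index 0) by default, matching
    the convention of reporting over listed anatomical regions.  Classes
    absent from both prediction and truth score 1.0 (flagged by a warning).
    """
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if pred_labels.shape != true_labels.shape:
        raise ValueError("shape mismatch")
    dices, ious = [], []
    for k in range(K):
        d, i = dice_iou(pred_labels == k, true_labels == k)
        if not np.any(pred_labels == k) and not np.any(true_labels == k):
            warnings.warn(f"class {k} absent from prediction and truth",
                          stacklevel=2)
        dices.append(d)
        ious.append(i)
    lo = 0 if include_background else 1
    return MetricsReport(
        per_class_dice=dices,
        per_class_iou=ious,
        mean_dice=float(np.mean(dices[lo:])),
        mean_iou=float(np.mean(ious[lo:])),
    )


def stability(values: Sequence[float]) -> StabilitySummary:
    """Mean and population standard deviation of a score series."""
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise ValueError("need at least two values for a stability summary")
    arr = np.asarray(vals)
    return StabilitySummary(values=vals, mean=float(arr.mean()),
                            std=float(arr.std(ddof=0)))


def render_scores_percent(report: MetricsReport) -> pd.DataFrame:
    """Scores as a one-row table in percent, 2 decimals (3 for std-like cells)."""
    row = {}
    for k, v in report.to_dict().items():
        if isinstance(v, float) and np.isfinite(v):
            row[k] = round(100 * v, 2)
    return pd.DataFrame([row])
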