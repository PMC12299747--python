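"""Evaluation metrics: pixel segmentation quality and grading accuracy.

Pixel metrics operate on a (k+1)x(k+1) confusion matrix over the k object
classes plus background (row = true class, column = predicted class):

* ``PA``   — overall pixel accuracy, trace / total;
* ``MPA``  — mean over classes of the per-class (row) accuracy;
* ``MIoU`` — mean over classes of ``p_ii / (row_i + col_i - p_ii)``.

The background row/column is included by default; ``include_background=
False`` restricts the class mean to the object classes.

Detection-style precision/recall/F1 accept either instance counts (one
count per object) or pixel counts — the formulas are identical, the mode
flag only documents provenance.

Grading accuracy is the *unweighted mean of per-grade correct rates*:
``100 * (n1/N1 + n2/N2 + n3/N3) / 3``.  With balanced grade totals this
equals plain accuracy, but it is robust to imbalanced batches.  Reported
figures are rounded half-up to 2 decimals, matching how such tables are
conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np

from .errors import UndefinedMetricError
from .mask import LabelMask


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as grading tables are printed."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PixelConfusion:
    """Pixel confusion matrix, ``p[i, j]`` = true class i predicted as j."""

    p: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.p, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] == 0:
            raise ValueError(f"confusion matrix must be square, got shape {arr.shape}")
        if (arr < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "p", arr)

    @property
    def total(self) -> int:
        return int(self.p.sum())


def confusion_from_masks(
    truth: LabelMask, pred: LabelMask, n_classes: int = 3
) -> PixelConfusion:
    """Accumulate the pixel confusion matrix of one predicted mask."""
    if truth.labels.shape != pred.labels.shape:
        raise ValueError("truth and prediction differ in shape")
    idx = truth.labels.astype(np.int64) * n_classes + pred.labels.astype(np.int64)
    counts = np.bincount(idx.ravel(), minlength=n_classes * n_classes)
    return PixelConfusion(counts.reshape(n_classes, n_classes))


@dataclass(frozen=True)
class DetectionCounts:
    """TP/FP/FN tallies for one class, instance- or pixel-level."""

    TP: int
    FP: int
    FN: int
    mode: Literal["instance", "pixel"] = "instance"

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")


def precision_recall_f1(c: DetectionCounts) -> tuple[float, float, float]:
    """Precision, recall and F1 from TP/FP/FN counts.

    Raises
    ------
    UndefinedMetricError
        When TP+FP = 0 or TP+FN = 0.
    """
    if c.TP + c.FP == 0 or c.TP + c.FN == 0:
        raise UndefinedMetricError("precision/recall undefined: zero denominator")
    precision = c.TP / (c.TP + c.FP)
    recall = c.TP / (c.TP + c.FN)
    f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def _class_indices(p: np.ndarray, include_background: bool) -> range:
    return range(0 if include_background else 1, p.shape[0])


def miou(conf: PixelConfusion, include_background: bool = True) -> float:
    """Mean intersection-over-union across classes."""
    p = conf.p
    ious = []
    for i in _class_indices(p, include_background):
        union = p[i, :].sum() + p[:, i].sum() - p[i, i]
        if union == 0:
            raise UndefinedMetricError(f"class {i} absent from truth and prediction")
        ious.append(p[i, i] / union)
    if not ious:
        raise UndefinedMetricError("no classes to average")
    return float(np.mean(ious))


def pa(conf: PixelConfusion) -> float:
    """Overall pixel accuracy: trace over total."""
    if conf.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return float(np.trace(conf.p) / conf.total)


def mpa(conf: PixelConfusion, include_background: bool = True) -> float:
    """Mean per-class pixel accuracy (mean of row accuracies)."""
    p = conf.p
    accs = []
    for i in _class_indices(p, include_background):
        row = p[i, :].sum()
        if row == 0:
            raise UndefinedMetricError(f"class {i} has no true pixels")
        accs.append(p[i, i] / row)
    if not accs:
        raise UndefinedMetricError("no classes to average")
    return float(np.mean(accs))


@dataclass(frozen=True)
class GradeCounts:
    """Per-grade specimen totals and correct-classification counts."""

    totals: tuple[int, int, int]    # N1, N2, N3
    correct: tuple[int, int, int]   # n1, n2, n3

    def __post_init__(self) -> None:
        for n_i, N_i in zip(self.correct, self.totals):
            if not 0 <= n_i <= N_i:
                raise ValueError(f"need 0 <= correct <= total, got {n_i}/{N_i}")


def grading_accuracy(g: GradeCounts, ndigits: int | None = 2) -> float:
    """Unweighted mean of per-grade correct rates, as a percentage.

    Raises
    ------
    UndefinedMetricError
        When any grade total is zero.
    """
    if any(N == 0 for N in g.totals):
        raise UndefinedMetricError("grading accuracy undefined: a grade has zero specimens")
    value = 100.0 * sum(n / N for n, N in zip(g.correct, g.totals)) / 3.0
    return round_half_up(value, ndigits) if ndigits is not None else value


def mean_reported_accuracy(accuracies: Sequence[float], ndigits: int = 2) -> float:
    """Average of already-reported (2-decimal) accuracy figures.

    Summary rows in grading tables average the *printed* per-group
    accuracies; averaging the unrounded rates can differ in the last
    decimal.
    """
    vals = [round_half_up(a, ndigits) for a in accuracies]
    return round_half_up(float(np.mean(vals)), ndigits)
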