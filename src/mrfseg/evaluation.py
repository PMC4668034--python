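"""Segmentation scoring against ground-truth label maps.

The headline score is the macro F1: the harmonic mean of the macro-averaged
(class-mean) precision and recall over the three classes.  The alternative
convention — the mean of the three per-class F1 scores — differs in general
and is reported alongside in verbose output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_stack import LabelMap

N_CLASSES = 3


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 voxel counts; rows index the truth label, columns the prediction."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_CLASSES, N_CLASSES) or (c < 0).any():
            raise ValueError("confusion matrix must be 3x3 with non-negative counts")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class Scores:
    precision: tuple[float, float, float]
    recall: tuple[float, float, float]
    f1: tuple[float, float, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    #: mean of the per-class F1 scores (the other common "macro F1")
    mean_class_f1: float


def confusion_matrix(pred: LabelMap, truth: LabelMap) -> ConfusionMatrix:
    """Count voxels per (truth, prediction) label pair."""
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    idx = truth.labels.ravel().astype(np.int64) * N_CLASSES + pred.labels.ravel()
    counts = np.bincount(idx, minlength=N_CLASSES**2).reshape(N_CLASSES, N_CLASSES)
    return ConfusionMatrix(counts)


def macro_f1(cm: ConfusionMatrix, labels: tuple = (0, 1, 2)) -> Scores:
    """Per-class precision/recall/F1 and their macro summaries.

    Zero denominators (a class absent from prediction and/or truth) yield
    precision/recall of 0 for that class — conservative for small classes.
    ``labels`` restricts the macro averages to a class subset: binary
    single-channel ground truth is scored over (0, 1) so the structurally
    empty third class does not enter the average.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(np.float64)
    diag = np.diag(c)
    colsum = c.sum(axis=0)
    rowsum = c.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(colsum > 0, diag / colsum, 0.0)
        rec = np.where(rowsum > 0, diag / rowsum, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    sel = list(labels)
    mp = float(prec[sel].mean())
    mr = float(rec[sel].mean())
    mf1 = 2 * mp * mr / (mp + mr) if mp + mr > 0 else 0.0
    return Scores(tuple(prec), tuple(rec), tuple(f1), mp, mr, float(mf1),
                  float(f1[sel].mean()))


def score_labelmaps(pred: LabelMap, truth: LabelMap,
                    labels: tuple = (0, 1, 2)) -> Scores:
    """Convenience wrapper: confusion matrix + macro F1 in one call."""
    return macro_f1(confusion_matrix(pred, truth), labels=labels)
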