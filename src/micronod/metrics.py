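"""Evaluation metrics for two-class micro-nodule discrimination.

Class 1 is the micro-nodule ("positive") class, class 0 the non-nodule
class.  The headline figure of merit is the *average F-score*: the sum over
both classes of P·R/(P+R), which for two classes is algebraically identical
to the macro-averaged F1 (each class term is half the class F1).  Accuracy,
sensitivity (recall of class 1) and the area under the ROC curve complete
the report.

All metrics are returned as fractions in [0, 1]; result tables multiply by
100 when a percentage column is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionTable",
    "ROCData",
    "MetricReport",
    "confusion_from_scores",
    "precision_c",
    "recall_c",
    "average_f_score",
    "accuracy",
    "sensitivity",
    "roc_and_auc",
    "metric_report",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 confusion counts; class 1 (micro-nodule) is positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ROCData:
    """An ROC curve as ordered (threshold, FPR, TPR) points.

    The first point carries threshold +inf and sits at (0, 0); the last
    carries threshold -inf and sits at (1, 1).  FPR and TPR are
    non-decreasing along the curve.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.thresholds) == len(self.fpr) == len(self.tpr)):
            raise ValueError("ROC coordinate arrays must have equal length")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC curve must be monotone")


@dataclass(frozen=True)
class MetricReport:
    """The four reported metrics, each a fraction in [0, 1]."""

    accuracy: float
    f_score: float
    sensitivity: float
    auc: float

    def __post_init__(self) -> None:
        for name in ("accuracy", "f_score", "sensitivity", "auc"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of [0, 1]: {v}")

    def as_percent_row(self) -> dict[str, float]:
        """Row with the standard result-table column set, values x100."""
        return {
            "F-score (%)": 100.0 * self.f_score,
            "Accuracy (%)": 100.0 * self.accuracy,
            "Sensitivity (%)": 100.0 * self.sensitivity,
            "AUC (%)": 100.0 * self.auc,
        }


def _check_labels_scores(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D sequences")
    if y.size == 0:
        raise ValueError("empty input")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0 = non-nodule, 1 = micro-nodule)")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    return y.astype(int), s


def confusion_from_scores(labels, scores, threshold: float = 0.5) -> ConfusionTable:
    """Threshold class-1 scores into a confusion table.

    A score equal to the threshold predicts class 1 (ties go to positive).
    """
    y, s = _check_labels_scores(labels, scores)
    pred = s >= threshold
    return ConfusionTable(
        tp=int(np.sum((y == 1) & pred)),
        fp=int(np.sum((y == 0) & pred)),
        fn=int(np.sum((y == 1) & ~pred)),
        tn=int(np.sum((y == 0) & ~pred)),
    )


def precision_c(ct: ConfusionTable, class_id: int) -> float:
    """Per-class precision; a zero denominator yields 0 so sums stay total."""
    if class_id == 1:
        num, den = ct.tp, ct.tp + ct.fp
    elif class_id == 0:
        num, den = ct.tn, ct.tn + ct.fn
    else:
        raise ValueError(f"class_id must be 0 or 1, got {class_id}")
    return num / den if den else 0.0


def recall_c(ct: ConfusionTable, class_id: int) -> float:
    """Per-class recall; a zero denominator yields 0."""
    if class_id == 1:
        num, den = ct.tp, ct.tp + ct.fn
    elif class_id == 0:
        num, den = ct.tn, ct.tn + ct.fp
    else:
        raise ValueError(f"class_id must be 0 or 1, got {class_id}")
    return num / den if den else 0.0


def average_f_score(ct: ConfusionTable) -> float:
    """Sum over both classes of P_C*R_C/(P_C+R_C) (== two-class macro F1)."""
    if ct.total == 0:
        raise ValueError("confusion table is empty")
    total = 0.0
    for c in (0, 1):
        p, r = precision_c(ct, c), recall_c(ct, c)
        if p + r > 0:
            total += (p * r) / (p + r)
    return total


def accuracy(ct: ConfusionTable) -> float:
    """Fraction of all patches classified correctly."""
    if ct.total == 0:
        raise ValueError("confusion table is empty")
    return (ct.tp + ct.tn) / ct.total


def sensitivity(ct: ConfusionTable) -> float:
    """True-positive rate: recall of the micro-nodule class."""
    return recall_c(ct, 1)


def roc_and_auc(labels, scores) -> tuple[ROCData, float]:
    """ROC curve and trapezoidal AUC.

    Thresholds sweep the unique scores in descending order; tied scores
    advance jointly, which makes the trapezoidal area equal to the
    probability that a random positive outscores a random negative, with
    half-credit for exact ties.
    """
    y, s = _check_labels_scores(labels, scores)
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")

    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    # indices where the (descending) score strictly drops: one ROC vertex per
    # distinct threshold, ties advanced jointly
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.r_[distinct, y.size - 1]
    tps = np.cumsum(y_sorted == 1)[cut]
    fps = np.cumsum(y_sorted == 0)[cut]

    thresholds = np.r_[np.inf, s_sorted[cut], -np.inf]
    tpr = np.r_[0.0, tps / n_pos, 1.0]
    fpr = np.r_[0.0, fps / n_neg, 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCData(thresholds=thresholds, fpr=fpr, tpr=tpr), auc


def metric_report(labels, scores, threshold: float = 0.5) -> MetricReport:
    """Accuracy, average F-score, sensitivity and AUC from scored patches."""
    ct = confusion_from_scores(labels, scores, threshold)
    _, auc = roc_and_auc(labels, scores)
    return MetricReport(
        accuracy=accuracy(ct),
        f_score=average_f_score(ct),
        sensitivity=sensitivity(ct),
        auc=auc,
    )
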