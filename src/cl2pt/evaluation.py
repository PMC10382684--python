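"""Prediction-performance metrics: rank AUC, confusion rates, repeat summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets_io import DataError


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the tie-aware rank (Mann-Whitney) estimator.

    Equals P(score+ > score-) + 0.5 * P(tie) over positive-negative pairs.
    The rank form handles the heavy score ties produced by KNN vote
    fractions without ROC interpolation ambiguity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise DataError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class ConfusionReport:
    """Accuracy and error rates with explicit counts (auditable at small n)."""

    accuracy: float
    fpr: float | None  # None when no negatives in truth
    fnr: float | None  # None when no positives in truth
    fp: int
    fn: int
    n_pos: int
    n_neg: int
    n: int

    def fnr_str(self) -> str:
        if self.fnr is None:
            return "undefined"
        return f"{self.fnr:.2f} ({self.fn}/{self.n_pos})"

    def fpr_str(self) -> str:
        if self.fpr is None:
            return "undefined"
        return f"{self.fpr:.2f} ({self.fp}/{self.n_neg})"


def confusion_metrics(pred: np.ndarray, truth: np.ndarray) -> ConfusionReport:
    """Accuracy, FPR = FP/negatives and FNR = FN/positives with counts."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise DataError("prediction and truth vectors must have equal length")
    fp = int(((pred == 1) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    n = len(truth)
    return ConfusionReport(
        accuracy=float(1.0 - (fp + fn) / n),
        fpr=None if n_neg == 0 else fp / n_neg,
        fnr=None if n_pos == 0 else fn / n_pos,
        fp=fp,
        fn=fn,
        n_pos=n_pos,
        n_neg=n_neg,
        n=n,
    )


def repeat_summary(values: np.ndarray) -> tuple[float, float]:
    """Mean and standard error (sd(ddof=1)/sqrt(n)) over repeated runs."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DataError("repeat summary needs at least 2 values")
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))


@dataclass
class EvaluationReport:
    """Full report for one predictor on one target cohort."""

    auc_mean: float
    auc_se: float
    accuracy: float
    fpr: float | None
    fnr: float | None
    confusion: ConfusionReport
    n: int
    cutoff_used: float

    def to_dict(self) -> dict:
        return {
            "auc_mean": self.auc_mean,
            "auc_se": self.auc_se,
            "accuracy": self.accuracy,
            "fpr": self.fpr,
            "fpr_str": self.confusion.fpr_str(),
            "fnr": self.fnr,
            "fnr_str": self.confusion.fnr_str(),
            "n": self.n,
            "cutoff_used": self.cutoff_used,
        }
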