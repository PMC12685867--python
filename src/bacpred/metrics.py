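"""Binary-classification metrics from confusion counts, plus rank-based AUC.

Accuracy, MCC, recall, precision and F1 are computed directly from the
confusion matrix; AUC uses the Mann-Whitney rank formulation with average
ranks for ties.  Degenerate denominators (e.g. precision with no positive
predictions) yield 0 together with a warning flag rather than NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in (("tp", self.tp), ("tn", self.tn), ("fp", self.fp), ("fn", self.fn)):
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass(frozen=True)
class MetricsReport:
    confusion: ConfusionMatrix
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auc: float | None = None
    warnings: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict:
        d = {
            "tp": self.confusion.tp, "tn": self.confusion.tn,
            "fp": self.confusion.fp, "fn": self.confusion.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "mcc": self.mcc,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if self.warnings:
            d["warnings"] = list(self.warnings)
        return d


def metrics_from_confusion(cm: ConfusionMatrix, auc: float | None = None) -> MetricsReport:
    """Accuracy, MCC, recall, precision, F1 from confusion counts."""
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    warnings: list[str] = []
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    accuracy = (tp + tn) / cm.total

    if tp + fp == 0:
        precision = 0.0
        warnings.append("precision undefined (no positive predictions); reported 0")
    else:
        precision = tp / (tp + fp)

    if tp + fn == 0:
        recall = 0.0
        warnings.append("recall undefined (no positive samples); reported 0")
    else:
        recall = tp / (tp + fn)

    if precision + recall == 0:
        f1 = 0.0
        warnings.append("F1 undefined; reported 0")
    else:
        f1 = 2 * precision * recall / (precision + recall)

    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0:
        mcc = 0.0
        warnings.append("MCC undefined (zero denominator); reported 0")
    else:
        mcc = (tp * tn - fp * fn) / denom

    return MetricsReport(
        confusion=cm, accuracy=accuracy, precision=precision, recall=recall,
        f1=f1, mcc=mcc, auc=auc, warnings=tuple(warnings),
    )


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann-Whitney statistic with tie correction.

    AUC = (sum of positive ranks - n_pos(n_pos+1)/2) / (n_pos * n_neg),
    ranks averaged over ties, which counts tied score pairs as half
    concordant.  All-tied scores give exactly 0.5.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
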