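"""Multiclass classification metrics from confusion counts.

Implements the evaluation suite used throughout the package: per-class
precision, recall and F1 via a one-vs-rest reduction of the confusion
matrix, overall accuracy (trace / total), Cohen's kappa, and the Matthews
correlation coefficient.  For C > 2 classes MCC uses the covariance
(Gorodkin) generalization, which reduces exactly to the familiar binary
formula ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))`` at C = 2.

Ratios with a zero denominator (degenerate classes) return 0 by convention
so every metric is a total function of the confusion matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "confusion_matrix",
    "per_class_counts",
    "precision_recall_f1",
    "accuracy",
    "cohen_kappa",
    "mcc",
    "macro_ovr_mcc",
    "MetricsReport",
    "full_report",
]


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int | None = None
) -> np.ndarray:
    """C x C count matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if y_true.size == 0:
        raise ValueError("at least one sample is required")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _check_cm(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    return cm.astype(np.int64)


def per_class_counts(cm: np.ndarray, c: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, FN, TN) for class ``c``."""
    cm = _check_cm(cm)
    if not 0 <= c < cm.shape[0]:
        raise ValueError(f"class index {c} out of range")
    tp = int(cm[c, c])
    fp = int(cm[:, c].sum() - tp)
    fn = int(cm[c, :].sum() - tp)
    tn = int(cm.sum() - tp - fp - fn)
    return tp, fp, fn, tn


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1 = harmonic mean; 0 on 0/0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def accuracy(cm: np.ndarray) -> float:
    """Fraction of correctly classified samples: trace / total."""
    cm = _check_cm(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def cohen_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement kappa = (p0 - pe) / (1 - pe).

    ``p0`` is the observed agreement (trace/total) and ``pe`` the agreement
    expected from the marginals alone.  If the marginals force perfect
    chance agreement (pe = 1), kappa is 1 when agreement is perfect and 0
    otherwise.
    """
    cm = _check_cm(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p0 = np.trace(cm) / total
    rows = cm.sum(axis=1)
    cols = cm.sum(axis=0)
    pe = float(np.dot(rows, cols)) / (total * total)
    if math.isclose(pe, 1.0, abs_tol=1e-15):
        return 1.0 if math.isclose(p0, 1.0, abs_tol=1e-15) else 0.0
    return float((p0 - pe) / (1.0 - pe))


def mcc(cm: np.ndarray) -> float:
    """Matthews correlation coefficient; covariance form for any class count.

    ``(c*s - t.p) / sqrt((s^2 - p.p)(s^2 - t.t))`` with c = trace, s = total,
    t = row sums (true counts), p = column sums (predicted counts).  At
    C = 2 this equals the classical TP/TN/FP/FN expression identically.
    Returns 0 when either variance term vanishes.
    """
    cm = _check_cm(cm)
    s = cm.sum()
    if s == 0:
        raise ValueError("empty confusion matrix")
    t = cm.sum(axis=1).astype(np.float64)
    p = cm.sum(axis=0).astype(np.float64)
    c = float(np.trace(cm))
    cov_tp = c * s - float(np.dot(t, p))
    cov_pp = float(s) ** 2 - float(np.dot(p, p))
    cov_tt = float(s) ** 2 - float(np.dot(t, t))
    denom = math.sqrt(cov_pp) * math.sqrt(cov_tt)
    if denom == 0.0:
        return 0.0
    return cov_tp / denom


def macro_ovr_mcc(cm: np.ndarray) -> float:
    """Macro average of the binary MCC of each one-vs-rest collapse."""
    cm = _check_cm(cm)
    values = []
    for c in range(cm.shape[0]):
        tp, fp, fn, tn = per_class_counts(cm, c)
        num = tp * tn - fp * fn
        den = math.sqrt(
            float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
        )
        values.append(num / den if den > 0 else 0.0)
    return float(np.mean(values))


@dataclass
class MetricsReport:
    """Per-class and overall metrics for one set of predictions."""

    confusion: np.ndarray
    class_names: list[str]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    kappa: float
    mcc: float
    macro_precision: float = field(init=False)
    macro_recall: float = field(init=False)
    macro_f1: float = field(init=False)

    def __post_init__(self) -> None:
        self.macro_precision = float(np.mean(self.precision))
        self.macro_recall = float(np.mean(self.recall))
        self.macro_f1 = float(np.mean(self.f1))

    def to_frame(self) -> pd.DataFrame:
        """Per-class table with Precision / Recall / F1-score columns."""
        return pd.DataFrame(
            {
                "Class": self.class_names,
                "Precision": self.precision,
                "Recall": self.recall,
                "F1-score": self.f1,
            }
        )

    def to_dict(self) -> dict:
        return {
            "classes": list(self.class_names),
            "confusion_matrix": self.confusion.tolist(),
            "precision": [float(v) for v in self.precision],
            "recall": [float(v) for v in self.recall],
            "f1": [float(v) for v in self.f1],
            "accuracy": float(self.accuracy),
            "cohen_kappa": float(self.kappa),
            "mcc": float(self.mcc),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __str__(self) -> str:
        lines = [self.to_frame().to_string(index=False, float_format="%.4f")]
        lines.append(f"Accuracy          {self.accuracy:.4f}")
        lines.append(f"Cohen's Kappa     {self.kappa:.4f}")
        lines.append(f"MCC               {self.mcc:.4f}")
        return "\n".join(lines)


def full_report(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    class_names: list[str] | None = None,
) -> MetricsReport:
    """Build a :class:`MetricsReport` from paired label vectors."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    n_classes = int(max(y_true.max(), y_pred.max())) + 1 if y_true.size else 0
    if class_names is not None:
        n_classes = max(n_classes, len(class_names))
    cm = confusion_matrix(y_true, y_pred, n_classes=n_classes)
    if class_names is None:
        class_names = [f"class_{i}" for i in range(n_classes)]
    prec = np.empty(n_classes)
    rec = np.empty(n_classes)
    f1 = np.empty(n_classes)
    for c in range(n_classes):
        tp, fp, fn, _ = per_class_counts(cm, c)
        prec[c], rec[c], f1[c] = precision_recall_f1(tp, fp, fn)
    return MetricsReport(
        confusion=cm,
        class_names=list(class_names),
        precision=prec,
        recall=rec,
        f1=f1,
        accuracy=accuracy(cm),
        kappa=cohen_kappa(cm),
        mcc=mcc(cm),
    )
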