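"""Confusion-matrix construction and binary evaluation metrics.

The positive class is "adulterated" (label 1): TP counts adulterated samples
flagged as adulterated, TN pure samples cleared as pure, FP pure samples
wrongly flagged, FN adulterated samples missed.  From these counts:

    ACC = (TP + TN) / (TP + TN + FP + FN) * 100%
    PRE = TP / (TP + FP) * 100%
    REC = TP / (TP + FN) * 100%
    F1  = 2 * PRE * REC / (PRE + REC)        (unit scale, not percent)

A zero denominator yields ``None`` for that metric rather than an exception.
Reported rounding convention: percentages to 2 decimals, F1 to 4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "compute_metrics",
    "f1_from_pre_rec",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """ACC/PRE/REC as percentages in [0, 100], F1 on the unit scale.

    ``None`` marks a metric whose denominator was zero.
    """

    acc: float | None
    pre: float | None
    rec: float | None
    f1: float | None

    def rounded(self) -> "MetricsReport":
        def r(v, nd):
            return None if v is None else round(v, nd)

        return MetricsReport(r(self.acc, 2), r(self.pre, 2), r(self.rec, 2), r(self.f1, 4))

    def to_dict(self) -> dict:
        return {"acc": self.acc, "pre": self.pre, "rec": self.rec, "f1": self.f1}


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with adulterated (1) as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall (percent) and F1 from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    pre = 100.0 * cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp > 0 else None
    rec = 100.0 * cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    f1 = f1_from_pre_rec(pre, rec)
    return MetricsReport(acc=acc, pre=pre, rec=rec, f1=f1)


def f1_from_pre_rec(pre: float | None, rec: float | None) -> float | None:
    """Harmonic mean of precision and recall (percent in, unit scale out)."""
    if pre is None or rec is None or pre + rec == 0:
        return None
    return 2.0 * pre * rec / (pre + rec) / 100.0


def evaluate(model, spectra) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix and metrics of a model on a labelled SpectraSet."""
    y_pred = model.predict(spectra.absorbance)
    cm = confusion_matrix(spectra.labels, y_pred)
    return cm, compute_metrics(cm)


def write_metrics_json(cm: ConfusionMatrix, report: MetricsReport, path: str | Path) -> None:
    """Write rounded metrics plus raw confusion counts as deterministic JSON."""
    payload = {
        "confusion": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
        "metrics": report.rounded().to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
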