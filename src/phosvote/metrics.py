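"""Confusion-matrix bookkeeping and threshold-free ranking evaluation.

Binary phosphorylation-site predictors are scored with the four standard
two-class measures — sensitivity (Sn), specificity (Sp), accuracy (ACC) and
the Matthews correlation coefficient (MCC) — plus ROC curves and the area
under them for score-valued (e.g. weighted-vote) predictors.

Conventions
-----------
* Sn = TP/(TP+FN), Sp = TN/(TN+FP), ACC = (TP+TN)/total,
  MCC = (TP·TN − FN·FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)).
* MCC with any zero denominator factor is defined as 0.
* Sn (resp. Sp) is ``None`` when no positive (resp. negative) sites exist.
* Rates are fractions in [0, 1] internally; reports format them as
  percentages with one decimal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "PerformanceReport",
    "RocCurve",
    "confusion_counts",
    "performance",
    "evaluate_binary",
    "roc_curve",
]


def _as_binary_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    uniq = np.unique(arr)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError(f"{name} must contain only 0/1 entries, found {uniq}")
    return arr.astype(np.int64)


@dataclass(frozen=True)
class ConfusionCounts:
    """The 2x2 confusion table of a binary predictor against true labels."""

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
class PerformanceReport:
    """Sn/Sp/ACC/MCC (and optionally AUC) for one predictor.

    ``sn`` or ``sp`` is None when the corresponding class is absent from the
    evaluated data.
    """

    sn: float | None
    sp: float | None
    acc: float
    mcc: float
    auc: float | None = None
    name: str | None = None

    def as_dict(self) -> dict:
        return {
            "predictor": self.name,
            "Sn": self.sn,
            "Sp": self.sp,
            "ACC": self.acc,
            "MCC": self.mcc,
            "AUC": self.auc,
        }

    def format_row(self) -> str:
        """Tab-separated row with rates as percentages, one decimal."""

        def pct(v):
            return "NA" if v is None else f"{100.0 * v:.1f}"

        auc = "NA" if self.auc is None else f"{self.auc:.3f}"
        return "\t".join(
            [self.name or "", pct(self.sn), pct(self.sp), pct(self.acc),
             f"{self.mcc:.3f}", auc]
        )


@dataclass(frozen=True)
class RocCurve:
    """An ROC curve: ordered (FPR, TPR) points from (0,0) to (1,1) and its area."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    thresholds: tuple[float, ...]
    area: float

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr, self.tpr))


def confusion_counts(pred, labels) -> ConfusionCounts:
    """Tally TP/FP/FN/TN of binary predictions against binary labels."""
    p = _as_binary_array(pred, "pred")
    y = _as_binary_array(labels, "labels")
    if p.shape != y.shape:
        raise ValueError(
            f"pred and labels must have equal length ({p.size} != {y.size})"
        )
    tp = int(np.sum((p == 1) & (y == 1)))
    fp = int(np.sum((p == 1) & (y == 0)))
    fn = int(np.sum((p == 0) & (y == 1)))
    tn = int(np.sum((p == 0) & (y == 0)))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def performance(counts: ConfusionCounts, auc: float | None = None,
                name: str | None = None) -> PerformanceReport:
    """Compute Sn, Sp, ACC and MCC from confusion counts.

    MCC's denominator is sqrt of the product of the four marginal totals; if
    any of them is zero the coefficient is undefined and reported as 0.
    """
    if counts.total <= 0:
        raise ValueError("cannot compute performance of zero evaluated sites")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    pos, neg = tp + fn, tn + fp
    sn = tp / pos if pos > 0 else None
    sp = tn / neg if neg > 0 else None
    acc = (tp + tn) / counts.total
    denom = pos * neg * (tp + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fn * fp) / math.sqrt(denom)
    return PerformanceReport(sn=sn, sp=sp, acc=acc, mcc=mcc, auc=auc, name=name)


def evaluate_binary(pred, labels, name: str | None = None) -> PerformanceReport:
    """Convenience composition of :func:`confusion_counts` and :func:`performance`."""
    return performance(confusion_counts(pred, labels), name=name)


def roc_curve(scores, labels) -> RocCurve:
    """ROC curve of a real-valued score against binary labels.

    One operating point per distinct score threshold (ties collapse to one
    threshold), bracketed by the (0,0) and (1,1) endpoints; the area is the
    trapezoidal integral over the points. Positive calls are score >= t, so
    the curve of a meta-predictor evaluated at its own threshold passes
    through the (1-Sp, Sn) point of its thresholded predictions.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary_array(labels, "labels")
    if s.ndim != 1 or s.shape != y.shape:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC is undefined without both classes present")

    # Descending distinct thresholds: predictions are (score >= t).
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep the last index of each run of tied scores
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, y.size - 1]
    tpr = np.r_[0.0, tps[idx] / n_pos, 1.0]
    fpr = np.r_[0.0, fps[idx] / n_neg, 1.0]
    thresholds = np.r_[np.inf, s_sorted[idx], -np.inf]
    area = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=tuple(fpr), tpr=tuple(tpr),
                    thresholds=tuple(thresholds), area=area)


def reports_to_tsv(reports: Sequence[PerformanceReport]) -> str:
    """Serialize reports in the tabular shape used for predictor benchmarks."""
    header = "predictor\tSn\tSp\tACC\tMCC\tAUC"
    return "\n".join([header] + [r.format_row() for r in reports]) + "\n"


def reports_to_json(reports: Sequence[PerformanceReport]) -> str:
    return json.dumps([r.as_dict() for r in reports], indent=2)
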