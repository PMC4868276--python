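"""Binary-classification evaluation: confusion-count metrics and ROC/AUC.

MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
ACC = (TP+TN)/total, SEN = TP/(TP+FN), SPE = TN/(TN+FP), PRE = TP/(TP+FP).

Metric arithmetic is done on exact Python integers before the final
division, so there is no floating-point accumulation at any test scale. A
zero factor in MCC's denominator yields MCC = 0; an undefined precision
(TP+FP = 0) yields 0 with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ContractError


@dataclass(frozen=True)
class ConfusionCounts:
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

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class EvalReport:
    """The six headline metrics plus the ROC polyline behind the AUC."""

    mcc: float
    acc: float
    sen: float
    spe: float
    pre: float
    auc: float
    roc: list[tuple[float, float]]  # ordered (FPR, TPR), (0,0) .. (1,1)

    def to_dict(self) -> dict:
        return {
            "MCC": self.mcc, "ACC": self.acc, "SEN": self.sen,
            "SPE": self.spe, "PRE": self.pre, "AUC": self.auc,
        }


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """MCC, ACC, SEN, SPE and PRE from a confusion table."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = counts.total
    if total == 0:
        raise ContractError("empty confusion table")
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)  # exact ints
    mcc = (tp * tn - fp * fn) / math.sqrt(denom_sq) if denom_sq > 0 else 0.0
    acc = (tp + tn) / total
    sen = tp / (tp + fn) if tp + fn > 0 else 0.0
    spe = tn / (tn + fp) if tn + fp > 0 else 0.0
    if tp + fp > 0:
        pre = tp / (tp + fp)
    else:
        warnings.warn("precision undefined (no predicted positives); reporting 0", stacklevel=2)
        pre = 0.0
    return {"MCC": mcc, "ACC": acc, "SEN": sen, "SPE": spe, "PRE": pre}


def compute_auc(y_true, scores) -> tuple[float, list[tuple[float, float]]]:
    """ROC by threshold sweep over the unique decision values, area by the
    trapezoidal rule; tied scores are grouped (diagonal segments).

    Returns (AUC, ROC points); equals the Mann-Whitney statistic (fraction of
    positive>negative score pairs, ties counted half).
    """
    from sklearn.metrics import roc_curve

    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(y_true)
    if len(classes) < 2:
        raise ContractError("AUC requires both classes present")
    fpr, tpr, _ = roc_curve(y_true, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return auc, points


def evaluate(y_true, y_pred, scores) -> EvalReport:
    """Full report from labels, hard predictions and decision values."""
    counts = ConfusionCounts.from_predictions(y_true, y_pred)
    m = compute_metrics(counts)
    auc, roc = compute_auc(y_true, scores)
    return EvalReport(
        mcc=m["MCC"], acc=m["ACC"], sen=m["SEN"], spe=m["SPE"], pre=m["PRE"],
        auc=auc, roc=roc,
    )
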