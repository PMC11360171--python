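"""Confusion-matrix construction and classification metrics.

Sensitivity SE = TP/(TP+FN), specificity SP = TN/(TN+FP), balanced
accuracy BA = (SE+SP)/2, Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with MCC := 0 when any denominator factor vanishes (the common
convention), and AUC as the area under the ROC curve. A class absent
from the evaluated labels makes SE or SP genuinely undefined; those are
reported as NaN (missing), never silently as 0.

Predictions are thresholded at 0.5 with "p >= threshold -> active".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or v != int(v):
                raise ValueError(f"{f.name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    se: float
    sp: float
    ba: float
    mcc: float
    auc: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {"se": self.se, "sp": self.sp, "ba": self.ba, "mcc": self.mcc, "auc": self.auc}


def confusion(probabilities, labels, threshold: float = 0.5) -> ConfusionMatrix:
    """Tally a confusion matrix; prediction is active iff p >= threshold."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} probabilities vs {y.shape} labels")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (p >= threshold).astype(int)
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )


def mcc_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation; 0 by convention when a denominator factor is 0."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def roc_auc(probabilities, labels) -> float:
    """Trapezoidal ROC AUC (ties handled by the rank/Mann-Whitney equivalence)."""
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined: both classes must be present")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


def metric_set(cm: ConfusionMatrix, probabilities=None, labels=None) -> MetricSet:
    """SE, SP, BA, MCC from counts; AUC from probabilities when provided.

    SE (resp. SP) is NaN when no positive (resp. negative) chemical was
    evaluated — undefined, not zero.
    """
    se = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else math.nan
    sp = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else math.nan
    ba = (se + sp) / 2.0
    mcc = mcc_from_counts(cm.tp, cm.tn, cm.fp, cm.fn)
    auc = math.nan
    if probabilities is not None and labels is not None:
        auc = roc_auc(probabilities, labels)
    return MetricSet(se=se, sp=sp, ba=ba, mcc=mcc, auc=auc)


def aggregate_cv(metric_sets) -> pd.DataFrame:
    """Mean and sample SD per metric over CV folds (single fold -> SD 0)."""
    sets = list(metric_sets)
    if not sets:
        raise ValueError("need at least one metric set")
    frame = pd.DataFrame([m.as_dict() for m in sets])
    mean = frame.mean()
    sd = frame.std(ddof=1).fillna(0.0) if len(sets) > 1 else pd.Series(0.0, index=frame.columns)
    return pd.DataFrame({"mean": mean, "sd": sd})
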