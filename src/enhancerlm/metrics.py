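"""Confusion-matrix metrics and rank-based AUC.

Definitions:

    Sn  = TP / (TP + FN)                    sensitivity (recall on positives)
    Sp  = TN / (TN + FP)                    specificity
    Acc = (TP + TN) / (TP + TN + FP + FN)
    Bacc = (Sn + Sp) / 2                    balanced accuracy
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

AUC is computed as the tie-aware rank (Mann–Whitney) statistic: the fraction
of (positive, negative) pairs where the positive scores higher, ties counted
as 1/2.  This equals trapezoidal ROC integration but is directly checkable
against a pair-enumeration oracle.

Degenerate denominators yield NaN ("undefined") with a warning, except MCC
whose zero-denominator convention is 0.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("confusion counts are all zero")


@dataclass(frozen=True)
class MetricsReport:
    sn: float
    sp: float
    acc: float
    bacc: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict:
        d = {"Sn": self.sn, "Sp": self.sp, "Acc": self.acc,
             "Bacc": self.bacc, "MCC": self.mcc}
        if self.auc is not None:
            d["AUC"] = self.auc
        return d


def counts_from_predictions(labels, predicted) -> ConfusionCounts:
    """Confusion counts from true labels and predicted labels (both 0/1)."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predicted, dtype=int)
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """Derive Sn, Sp, Acc, Bacc and MCC from confusion counts.

    An AUC computed separately from scores may be attached.  A zero MCC
    denominator is reported as MCC = 0 with a warning.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sn = _ratio(tp, tp + fn, "Sn")
    sp = _ratio(tn, tn + fp, "Sp")
    acc = (tp + tn) / (tp + tn + fp + fn)
    bacc = (sn + sp) / 2.0
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        warnings.warn("MCC denominator zero; reporting MCC = 0", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    return MetricsReport(sn=sn, sp=sp, acc=acc, bacc=bacc, mcc=mcc, auc=auc)


def auc(labels, scores) -> float:
    """Tie-aware rank AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate(labels, scores, threshold: float = 0.55) -> MetricsReport:
    """Full report from true labels and predicted probabilities."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    counts = counts_from_predictions(y, (s > threshold).astype(int))
    return compute_metrics(counts, auc=auc(y, s))


def write_report(report: MetricsReport, path: str | Path) -> None:
    """Write a metrics report as JSON with fixed key names."""
    Path(path).write_text(json.dumps(report.as_dict(), indent=2) + "\n")
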