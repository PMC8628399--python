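"""Binary-classification metrics: ROC AUC, PR AUC, F1 and MCC.

Scores are case-probabilities or any monotone score; labels are 0 (control)
and 1 (case).  F1 and MCC are thresholded metrics; the default cut-off is 0.5
on the predicted case probability.  Degenerate denominators follow the usual
conventions (F1 and MCC return 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import precision_recall_curve

__all__ = ["ConfusionCounts", "MetricSet", "confusion", "roc_auc", "pr_auc", "f1", "mcc",
           "metric_set", "METRIC_NAMES"]

METRIC_NAMES = ("auc", "pr_auc", "f1", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    return labels, scores


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Tabulate a 2x2 confusion table: predicted case iff score >= threshold."""
    labels, scores = _check(labels, scores)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def roc_auc(labels, scores) -> float:
    """Rank-based AUC with midrank tie handling.

    Equals P(score_case > score_control) + 0.5 * P(tie), the Mann-Whitney
    statistic normalised by the number of case-control pairs.
    """
    labels, scores = _check(labels, scores)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: need at least one case and one control")
    ranks = rankdata(scores)  # midranks
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def pr_auc(labels, scores) -> float:
    """Area under the precision-recall curve, trapezoid rule on recall.

    The precision at recall 0 is carried over from the first attainable
    operating point (highest threshold) rather than pinned at 1.
    """
    labels, scores = _check(labels, scores)
    if (labels == 1).sum() == 0:
        raise ValueError("PR AUC undefined: need at least one case")
    precision, recall, _ = precision_recall_curve(labels, scores)
    # precision_recall_curve appends an anchor (precision=1, recall=0);
    # replace it with the first attainable precision
    precision = precision.copy()
    precision[-1] = precision[-2]
    # recall is decreasing, so the signed trapezoid integral is negative
    return float(-np.trapezoid(precision, recall))


def f1(c: ConfusionCounts) -> float:
    """F1 = 2tp / (2tp + fp + fn); 0 when the denominator vanishes."""
    denom = 2 * c.tp + c.fp + c.fn
    return 0.0 if denom == 0 else 2 * c.tp / denom


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


@dataclass(frozen=True)
class MetricSet:
    auc: float
    pr_auc: float
    f1: float
    mcc: float

    def as_dict(self) -> dict:
        return {"auc": self.auc, "pr_auc": self.pr_auc, "f1": self.f1, "mcc": self.mcc}


def metric_set(labels, scores, threshold: float = 0.5) -> MetricSet:
    """All four metrics from one (labels, scores) pair.

    Raises ValueError on single-class label vectors (the AUCs are undefined);
    callers evaluating random partitions should record the cell as missing.
    """
    c = confusion(labels, scores, threshold)
    return MetricSet(
        auc=roc_auc(labels, scores),
        pr_auc=pr_auc(labels, scores),
        f1=f1(c),
        mcc=mcc(c),
    )
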