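"""Confusion-matrix bookkeeping and the evaluation metrics reported with it.

Threshold-dependent metrics are computed from TP/TN/FP/FN counts:

* ``Sens = 100 * TP / P``  (true positive rate)
* ``Spec = 100 * TN / N``  (true negative rate)
* ``Acc  = 100 * (TP + TN) / (P + N)``
* ``MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``, defined
  as 0 when any factor of the denominator is 0 (a degenerate prediction
  carries no correlation).

AUROC is threshold-independent and computed from the rank statistic (the
normalized Mann–Whitney U with the average-rank tie convention), which equals
trapezoidal integration of the TPR–FPR curve over all thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies for one threshold."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.TN + self.FP


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity/specificity/accuracy in percent, MCC, AUROC, threshold."""

    sens: float
    spec: float
    acc: float
    mcc: float
    auroc: float | None = None
    threshold: float | None = None

    def as_dict(self) -> dict:
        return {
            "sens": self.sens,
            "spec": self.spec,
            "acc": self.acc,
            "mcc": self.mcc,
            "auroc": self.auroc,
            "threshold": self.threshold,
        }


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    """Tally the confusion matrix for the rule: predict positive iff score >= t."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError(f"scores {scores.shape} and labels {labels.shape} differ")
    pred = scores >= threshold
    actual = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & actual)),
        TN=int(np.sum(~pred & ~actual)),
        FP=int(np.sum(pred & ~actual)),
        FN=int(np.sum(~pred & actual)),
    )


def matthews_cc(c: ConfusionCounts) -> float:
    """MCC from counts, with the zero-denominator-is-zero convention."""
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / sqrt(denom)


def compute_metrics(
    c: ConfusionCounts, auroc: float | None = None, threshold: float | None = None
) -> MetricsReport:
    """Derive the threshold-dependent metric block from confusion counts."""
    if c.P == 0 or c.N == 0:
        raise ValueError("metrics require at least one positive and one negative")
    return MetricsReport(
        sens=100.0 * c.TP / c.P,
        spec=100.0 * c.TN / c.N,
        acc=100.0 * (c.TP + c.TN) / (c.P + c.N),
        mcc=matthews_cc(c),
        auroc=auroc,
        threshold=threshold,
    )


def compute_auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank statistic.

    Equals the fraction of (positive, negative) pairs ranked concordantly,
    counting ties as half — identical to trapezoidal integration of the
    TPR-FPR curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(scores)  # average ranks implement the tie-half convention
    u_stat = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u_stat / (n_pos * n_neg))


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """FPR/TPR pairs over all distinct thresholds (for plotting/export).

    Rows are (threshold, FPR, TPR), thresholds descending, endpoints included.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    rows = []
    for t in thresholds:
        c = confusion_at_threshold(scores, labels, t)
        rows.append((t, c.FP / c.N if c.N else 0.0, c.TP / c.P if c.P else 0.0))
    return np.asarray(rows)
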