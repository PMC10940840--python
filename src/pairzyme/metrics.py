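"""Classification metrics: ROC-AUC, PRC-AUC, confusion counts.

ROC-AUC is the area under TPR(FPR) over all thresholds, equivalently the
tie-corrected Mann-Whitney probability that a random positive outscores a
random negative; PRC-AUC is the area under the precision-recall step curve.
Both are delegated to scikit-learn; the test suite checks them against
exhaustive pair-counting / threshold-sweep oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .triads import POSITIVE


def _validate(scores, labels, need_both=True, need_pos=True):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if need_pos and not np.any(labels == 1):
        raise ValueError("no positive labels")
    if need_both and not np.any(labels == 0):
        raise ValueError("only one class present")
    return scores, labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (both classes required)."""
    scores, labels = _validate(scores, labels)
    return float(roc_auc_score(labels, scores))


def prc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall step curve (>= 1 positive required)."""
    scores, labels = _validate(scores, labels, need_both=False)
    return float(average_precision_score(labels, scores))


@dataclass(frozen=True)
class MetricReport:
    roc_auc: float
    prc_auc: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float = 0.5

    def __post_init__(self):
        n = self.tp + self.fp + self.tn + self.fn
        if n == 0:
            raise ValueError("empty report")


def report_from_scores(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> MetricReport:
    scores, labels = _validate(scores, labels)
    calls = scores > threshold
    tp = int(np.sum(calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    tn = int(np.sum(~calls & (labels == 0)))
    fn = int(np.sum(~calls & (labels == 1)))
    return MetricReport(
        roc_auc=roc_auc(scores, labels),
        prc_auc=prc_auc(scores, labels),
        accuracy=(tp + tn) / len(labels),
        tp=tp, fp=fp, tn=tn, fn=fn,
        threshold=threshold,
    )


def evaluate(net, triads, threshold: float = 0.5) -> MetricReport:
    """Score labeled triads in deterministic evaluation mode and summarize."""
    labels = np.array([1 if t.label == POSITIVE else 0 for t in triads])
    scores = net.score(list(triads))
    return report_from_scores(scores, labels, threshold=threshold)
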