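"""Ranked-edge evaluation metrics.

AUROC is computed via the Mann-Whitney statistic (probability that a random
positive outranks a random negative, ties counted half), using midranks from
:func:`scipy.stats.rankdata`.  AUPRC is step-wise average precision over
distinct score thresholds, with no interpolation; under tied scores each tie
group contributes its within-group precision, which equals the expected
precision under random tie ordering.  Thresholded metrics (ACC, MCC, TPR,
TNR, FDR, EPR) classify ``score >= threshold`` as positive.

EPR is reported as the misclassification rate (1 - ACC), reading it as an
"error prediction rate"; the network-inference literature also uses "early
precision ratio" for a different quantity, which is available separately as
:func:`early_precision_ratio`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedMetricError, UsageError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "auroc",
    "auprc",
    "confusion_counts",
    "thresholded_metrics",
    "metric_report",
    "early_precision_ratio",
]


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise UsageError("scores and labels must be equal-length 1-D arrays")
    if not np.isin(labels, (0, 1)).all():
        raise UsageError("labels must be binary (0/1)")
    return scores, labels.astype(np.intp)


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricReport:
    auroc: float
    auprc: float
    acc: float
    mcc: float
    tpr: float
    tnr: float
    fdr: float
    epr: float
    threshold: float

    def to_dict(self) -> dict:
        return asdict(self)


def auroc(scores, labels) -> float:
    """Probability that a uniformly chosen positive is scored above a
    uniformly chosen negative; tied scores count half."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC undefined: both classes must be present")
    ranks = rankdata(scores, method="average")
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Average precision: sum over descending score thresholds of
    precision-at-threshold times the recall increment."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise UndefinedMetricError("AUPRC undefined: no positive labels")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # indices where the score strictly drops = threshold boundaries
    boundaries = np.nonzero(np.diff(s))[0]
    idx = np.append(boundaries, s.size - 1)
    tp = np.cumsum(y)[idx].astype(np.float64)
    fp = (idx + 1) - tp
    precision = tp / (tp + fp)
    recall = tp / n_pos
    return float(np.sum(np.diff(np.concatenate([[0.0], recall])) * precision))


def confusion_counts(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    scores, labels = _validate(scores, labels)
    pred = scores >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (labels == 1))),
        FP=int(np.sum(pred & (labels == 0))),
        TN=int(np.sum(~pred & (labels == 0))),
        FN=int(np.sum(~pred & (labels == 1))),
    )


def thresholded_metrics(scores, labels, threshold: float = 0.5
                        ) -> tuple[ConfusionCounts, dict]:
    """Confusion counts at ``threshold`` plus ACC/MCC/TPR/TNR/FDR/EPR.

    MCC is 0 when any marginal of the confusion matrix is 0; FDR is 0 when
    nothing is predicted positive; EPR = (FP + FN) / total = 1 - ACC.
    """
    cc = confusion_counts(scores, labels, threshold)
    tp, fp, tn, fn = cc.TP, cc.FP, cc.TN, cc.FN
    total = cc.total
    acc = (tp + tn) / total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    tpr = tp / (tp + fn) if tp + fn else 0.0
    tnr = tn / (tn + fp) if tn + fp else 0.0
    fdr = fp / (tp + fp) if tp + fp else 0.0
    epr = (fp + fn) / total
    return cc, {"acc": acc, "mcc": float(mcc), "tpr": tpr, "tnr": tnr,
                "fdr": fdr, "epr": epr}


def metric_report(scores, labels, threshold: float = 0.5) -> MetricReport:
    """Full report: ranking metrics plus thresholded metrics at ``threshold``."""
    _, thr = thresholded_metrics(scores, labels, threshold)
    return MetricReport(
        auroc=auroc(scores, labels), auprc=auprc(scores, labels),
        threshold=threshold, **thr,
    )


def early_precision_ratio(scores, labels, top_k: int | None = None) -> float:
    """Precision among the ``top_k`` highest-scored pairs divided by the
    positive prevalence (the "early precision ratio" of the network-inference
    benchmarking literature).  ``top_k`` defaults to the number of positives."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise UndefinedMetricError("early precision undefined: no positives")
    k = top_k if top_k is not None else n_pos
    order = np.argsort(-scores, kind="stable")[:k]
    precision_at_k = labels[order].mean()
    prevalence = n_pos / labels.size
    return float(precision_at_k / prevalence)
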