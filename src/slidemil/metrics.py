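"""Slide-level evaluation metrics for imbalanced binary classification.

The positive class is tumour (label 1). Class imbalance is handled purely
through metric choice (MCC, macro F1, AUROC) rather than loss reweighting,
so these implementations are the ones the training protocol reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionCounts", "MetricsReport",
    "confusion_counts", "mcc", "roc_auroc", "f1_and_rates",
    "binary_cross_entropy", "evaluate_scores",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    precision_macro: float
    recall_macro: float
    f1_macro: float
    auroc: float
    mcc: float
    bce_loss: float
    precision_pos: float
    recall_pos: float
    precision_neg: float
    recall_neg: float
    fnr: float
    fpr: float
    undefined_ratios: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def confusion_counts(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Tabulate a 2x2 confusion table from P(tumour) scores.

    Predicted positive iff score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
    defined as 0 when any factor of the denominator is 0.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    factors = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if 0 in factors:
        return 0.0
    denom = np.sqrt(np.prod([float(f) for f in factors]))
    return float((tp * tn - fp * fn) / denom)


def roc_auroc(scores, labels):
    """ROC curve points and area, ties counted half.

    AUROC equals the probability that a random positive outscores a random
    negative (trapezoidal area over the threshold sweep).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC is undefined with a single class present")
    fpr, tpr, _ = roc_curve(labels, scores)
    area = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), area


def _ratio(num: int, den: int, name: str, flags: list) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def f1_and_rates(counts: ConfusionCounts) -> dict:
    """Per-class precision/recall, macro averages, F1, FNR and FPR.

    0/0 ratios are reported as 0 and listed under ``undefined_ratios``.
    """
    flags: list = []
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    precision_pos = _ratio(tp, tp + fp, "precision_pos", flags)
    recall_pos = _ratio(tp, tp + fn, "recall_pos", flags)
    precision_neg = _ratio(tn, tn + fn, "precision_neg", flags)
    recall_neg = _ratio(tn, tn + fp, "recall_neg", flags)
    f1_pos = (2 * precision_pos * recall_pos / (precision_pos + recall_pos)
              if (precision_pos + recall_pos) > 0 else 0.0)
    f1_neg = (2 * precision_neg * recall_neg / (precision_neg + recall_neg)
              if (precision_neg + recall_neg) > 0 else 0.0)
    return {
        "precision_pos": precision_pos,
        "recall_pos": recall_pos,
        "precision_neg": precision_neg,
        "recall_neg": recall_neg,
        "precision_macro": 0.5 * (precision_pos + precision_neg),
        "recall_macro": 0.5 * (recall_pos + recall_neg),
        "f1_macro": 0.5 * (f1_pos + f1_neg),
        "fnr": 1.0 - recall_pos,
        "fpr": _ratio(fp, fp + tn, "fpr", flags),
        "undefined_ratios": flags,
    }


def binary_cross_entropy(scores, labels) -> float:
    """Mean cross-entropy of P(tumour) scores against binary labels."""
    p = np.clip(np.asarray(scores, dtype=float), 1e-12, 1 - 1e-12)
    y = np.asarray(labels, dtype=float)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def evaluate_scores(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Assemble the full report from P(tumour) scores and true labels."""
    counts = confusion_counts(scores, labels, threshold)
    rates = f1_and_rates(counts)
    try:
        _, area = roc_auroc(scores, labels)
    except ValueError:
        area = float("nan")
    return MetricsReport(
        precision_macro=rates["precision_macro"],
        recall_macro=rates["recall_macro"],
        f1_macro=rates["f1_macro"],
        auroc=area,
        mcc=mcc(counts),
        bce_loss=binary_cross_entropy(scores, labels),
        precision_pos=rates["precision_pos"],
        recall_pos=rates["recall_pos"],
        precision_neg=rates["precision_neg"],
        recall_neg=rates["recall_neg"],
        fnr=rates["fnr"],
        fpr=rates["fpr"],
        undefined_ratios=rates["undefined_ratios"],
    )
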