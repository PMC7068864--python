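"""Binary-classifier evaluation: confusion counts, the five standard
metrics, and threshold-sweep ROC / precision-recall curves.

Malignant is the positive class throughout:

* precision  = TP / (TP + FP)
* recall     = sensitivity = TP / (TP + FN)
* specificity = TN / (TN + FP)
* F-measure  = harmonic mean of precision and recall
* accuracy   = (TP + TN) / (TP + TN + FP + FN)

``metrics`` keeps every value unrounded; ``rounded_report`` applies the
display convention under which the F-measure is the harmonic mean of the
*rounded* precision and recall.  Zero denominators raise
:class:`MetricUndefinedError` instead of silently returning 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (DegenerateTrainingError, DimensionError,
                     MetricUndefinedError, ParameterError)
from .synthgen import MALIGNANT


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")
        if self.total < 1:
            raise ParameterError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall_sensitivity: float
    specificity: float
    f_measure: float
    accuracy: float
    auc_roc: float | None = None
    auc_pr: float | None = None


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise MetricUndefinedError(f"{name} undefined: zero denominator")
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """All five metrics from confusion counts, unrounded."""
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    specificity = _ratio(c.tn, c.tn + c.fp, "specificity")
    if precision + recall == 0:
        raise MetricUndefinedError("f-measure undefined: precision+recall=0")
    f_measure = 2 * precision * recall / (precision + recall)
    accuracy = (c.tp + c.tn) / c.total
    return MetricsReport(precision=precision, recall_sensitivity=recall,
                         specificity=specificity, f_measure=f_measure,
                         accuracy=accuracy)


def rounded_report(c: ConfusionCounts, ndigits: int = 2) -> MetricsReport:
    """Metrics rounded to ``ndigits`` for display.

    Precision, recall, specificity and accuracy are rounded directly; the
    displayed F-measure is the harmonic mean of the already-rounded
    precision and recall, itself rounded — the convention under which
    published benign/malignant score tables in this line of work are
    internally consistent at 2 decimal places.
    """
    m = metrics(c)
    p = round(m.precision, ndigits)
    r = round(m.recall_sensitivity, ndigits)
    f = round(2 * p * r / (p + r), ndigits) if (p + r) > 0 else 0.0
    return MetricsReport(precision=p, recall_sensitivity=r,
                         specificity=round(m.specificity, ndigits),
                         f_measure=f, accuracy=round(m.accuracy, ndigits))


def confusion_from_predictions(labels, predictions,
                               positive: str = MALIGNANT) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with ``positive`` (default malignant) as the
    positive class."""
    labels = list(labels)
    predictions = list(predictions)
    if len(labels) != len(predictions):
        raise DimensionError("labels and predictions differ in length")
    tp = tn = fp = fn = 0
    for truth, pred in zip(labels, predictions):
        if truth == positive:
            tp += pred == positive
            fn += pred != positive
        else:
            fp += pred == positive
            tn += pred != positive
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def roc_pr_curves(labels, scores, positive: str = MALIGNANT) -> dict:
    """ROC and precision-recall curves by explicit threshold sweep.

    The threshold set is the unique score values plus +/- infinity
    endpoints; a score >= threshold predicts positive.  AUCs are trapezoid
    integrals.  Returns a dict with ``fpr``, ``tpr``, ``precision``,
    ``recall``, ``thresholds``, ``auc_roc``, ``auc_pr``.
    """
    y = np.array([1 if l == positive else 0 for l in labels])
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise DimensionError("labels and scores differ in length")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateTrainingError("both classes required for curves")

    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1], [-np.inf]))
    tpr, fpr, prec, rec = [], [], [], []
    for t in thresholds:
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
        rec.append(tp / n_pos)
        # precision at zero predictions conventionally 1 (PR curve anchor)
        prec.append(tp / (tp + fp) if (tp + fp) > 0 else 1.0)

    fpr = np.array(fpr)
    tpr = np.array(tpr)
    prec = np.array(prec)
    rec = np.array(rec)
    auc_roc = float(np.trapezoid(tpr, fpr))
    auc_pr = float(np.trapezoid(prec, rec))
    return {"fpr": fpr, "tpr": tpr, "precision": prec, "recall": rec,
            "thresholds": thresholds, "auc_roc": auc_roc, "auc_pr": auc_pr}


def report_to_dict(m: MetricsReport) -> dict:
    d = {"precision": m.precision, "recall_sensitivity": m.recall_sensitivity,
         "specificity": m.specificity, "f_measure": m.f_measure,
         "accuracy": m.accuracy}
    if m.auc_roc is not None:
        d["auc_roc"] = m.auc_roc
    if m.auc_pr is not None:
        d["auc_pr"] = m.auc_pr
    return d
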