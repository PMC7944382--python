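"""Classification metrics for rare-event prediction.

All metrics are computed from first principles (rank statistics and the 2x2
confusion table) rather than delegating to a library, so that undefined cases
-- single-class folds, zero predicted positives -- carry explicit flags and
fold summaries can choose how to treat them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "MetricBundle",
    "auc",
    "auprc",
    "auprc_interpolated",
    "brier",
    "confusion_metrics",
    "metric_bundle",
]


@dataclass
class MetricBundle:
    """The eight held-out metrics for one resample.

    Values are floats; a metric whose definition degenerates on the fold
    (e.g. AUC with a single class, PPV with no predicted positives) is
    recorded in ``undefined`` and its value is NaN except for PPV, which is
    reported as 0.0 so that fold summaries can include it (observed fold
    distributions of PPV legitimately contain exact zeros).
    """

    auc: float = np.nan
    auprc: float = np.nan
    accuracy: float = np.nan
    ppv: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    brier: float = np.nan
    kappa: float = np.nan
    undefined: set = field(default_factory=set)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "undefined"}

    @staticmethod
    def metric_names() -> list:
        return [f.name for f in fields(MetricBundle) if f.name != "undefined"]


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    return scores, labels.astype(int)


def auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (concordance) formulation.

    AUC = P(score of a random positive > score of a random negative)
        + 0.5 * P(tie).  Equivalent to the Mann-Whitney U statistic divided
    by n_pos * n_neg.  Returns NaN when only one class is present.
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    # midranks handle ties exactly
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(scores.size, dtype=float)
    sorted_scores = scores[order]
    i = 0
    r = 1.0
    while i < scores.size:
        j = i
        while j + 1 < scores.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        midrank = 0.5 * (r + r + (j - i))
        ranks[order[i : j + 1]] = midrank
        r += j - i + 1
        i = j + 1
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve as average precision.

    AP = sum over distinct thresholds of precision * recall increment, with
    tied scores grouped into a single threshold step.  The chance level of
    this metric equals the outcome prevalence.  NaN with no positives.
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        return np.nan
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # group ties: cumulative counts at the end of each tie block
    distinct = np.nonzero(np.r_[s[1:] != s[:-1], True])[0]
    tp = np.cumsum(y)[distinct]
    n_at = distinct + 1.0
    precision = tp / n_at
    recall = tp / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum(precision * (recall - recall_prev)))


def auprc_interpolated(scores, labels) -> float:
    """PR area by trapezoidal integration over the tie-grouped PR points.

    Exposed as an alternative convention; average precision (:func:`auprc`)
    is the default throughout the package.
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        return np.nan
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    distinct = np.nonzero(np.r_[s[1:] != s[:-1], True])[0]
    tp = np.cumsum(y)[distinct]
    precision = tp / (distinct + 1.0)
    recall = tp / n_pos
    recall = np.r_[0.0, recall]
    precision = np.r_[precision[0], precision]
    return float(np.trapezoid(precision, recall))


def brier(probabilities, labels) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p, y = _validate(probabilities, labels)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def confusion_metrics(labels_true, labels_pred) -> dict:
    """Accuracy, PPV, sensitivity, specificity and Cohen's kappa from the 2x2 table.

    Kappa is (p_o - p_e) / (1 - p_e) with the expected agreement p_e computed
    from the row/column marginals.  PPV with zero predicted positives is
    returned as 0.0 together with an ``"ppv"`` entry in ``undefined``;
    sensitivity/specificity with an empty truth class are NaN and flagged.
    """
    y = np.asarray(labels_true).astype(int)
    yhat = np.asarray(labels_pred).astype(int)
    if not (np.isin(y, [0, 1]).all() and np.isin(yhat, [0, 1]).all()):
        raise ValueError("labels must be binary 0/1")
    if y.shape != yhat.shape:
        raise ValueError("label vectors must have equal length")
    tp = int(((y == 1) & (yhat == 1)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    n = tp + fn + fp + tn
    undefined = set()
    accuracy = (tp + tn) / n
    if tp + fp == 0:
        ppv = 0.0
        undefined.add("ppv")
    else:
        ppv = tp / (tp + fp)
    if tp + fn == 0:
        sensitivity = np.nan
        undefined.add("sensitivity")
    else:
        sensitivity = tp / (tp + fn)
    if tn + fp == 0:
        specificity = np.nan
        undefined.add("specificity")
    else:
        specificity = tn / (tn + fp)
    p_o = accuracy
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / (n * n)
    if p_e == 1.0:
        kappa = np.nan
        undefined.add("kappa")
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return {
        "accuracy": accuracy,
        "ppv": ppv,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "kappa": kappa,
        "undefined": undefined,
    }


def metric_bundle(probabilities, labels_true, threshold: float = 0.5) -> MetricBundle:
    """Compute all eight metrics from predicted probabilities.

    Labels are assigned positive when probability >= threshold (inclusive at
    the boundary, so p = 0.5 classifies positive at the default threshold).
    """
    p, y = _validate(probabilities, labels_true)
    yhat = (p >= threshold).astype(int)
    cm = confusion_metrics(y, yhat)
    undefined = cm.pop("undefined")
    a = auc(p, y)
    ap = auprc(p, y)
    if np.isnan(a):
        undefined.add("auc")
    if np.isnan(ap):
        undefined.add("auprc")
    return MetricBundle(auc=a, auprc=ap, brier=brier(p, y), undefined=undefined, **cm)
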