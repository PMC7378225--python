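"""ROC construction, AUC, Youden-optimal cutoff and confusion metrics.

The empirical ROC is swept over all distinct score thresholds; the AUC is
the trapezoidal area, which equals the tie-corrected Mann-Whitney statistic
P(score+ > score-) + 0.5 * P(tie).  The operating point maximizes the Youden
index J = sensitivity + specificity - 1, with ties broken toward higher
specificity; the reported cutoff is the midpoint of the optimal threshold
interval, and a patient is called positive when score > cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ROCResult", "roc_auc", "optimal_cutoff", "confusion_metrics"]

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass
class ROCResult:
    """Threshold sweep plus AUC; cutoff fields filled by :func:`optimal_cutoff`."""

    thresholds: np.ndarray  # descending; sweep from all-negative to all-positive
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)
    cutoff: float | None = None
    metrics: dict | None = None  # at-cutoff sensitivity/specificity/PPV/NPV/accuracy


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D arrays of equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to build a ROC curve")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def roc_auc(scores, labels) -> ROCResult:
    """Empirical ROC over all distinct thresholds, with trapezoidal AUC.

    ``labels`` are binary with 1 = positive (expansion).  The curve starts at
    (sens, spec) = (0, 1) (threshold above every score) and ends at (1, 0).
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    # cumulative TP/FP at "score >= t" for each distinct threshold t
    distinct = np.flatnonzero(np.append(np.diff(s_sorted) != 0, True))
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]

    sens = np.concatenate(([0.0], tp / n_pos))
    fpr = np.concatenate(([0.0], fp / n_neg))
    spec = 1.0 - fpr
    thresholds = np.concatenate(([np.inf], s_sorted[distinct]))
    auc = float(np.trapezoid(sens, fpr))
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        scores=scores,
        labels=labels,
    )


def confusion_metrics(scores, labels, cutoff: float) -> dict:
    """Sensitivity, specificity, PPV, NPV and accuracy for ``score > cutoff``.

    PPV (NPV) is NaN when no positive (negative) call is made.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores > cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))

    def _ratio(a, b):
        return a / b if b > 0 else float("nan")

    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "accuracy": (tp + tn) / labels.size,
    }


def optimal_cutoff(roc: ROCResult) -> ROCResult:
    """Fill ``roc`` with the Youden-optimal cutoff and at-cutoff metrics.

    Candidate cutoffs are the midpoints between consecutive distinct scores
    plus one below the minimum and one above the maximum, so the reported
    cutoff sits in the middle of its optimal interval.  Ties on J break
    toward higher specificity (the larger cutoff).
    """
    if roc.scores is None or roc.labels is None:
        raise ValueError("ROCResult lacks the raw scores needed for cutoff search")
    uniq = np.unique(roc.scores)  # ascending
    candidates = np.concatenate(
        ([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0])
    )
    best = None
    for c in candidates:
        m = confusion_metrics(roc.scores, roc.labels, c)
        j = m["sensitivity"] + m["specificity"] - 1.0
        key = (j, m["specificity"], c)  # ties -> higher specificity -> higher cutoff
        if best is None or key > best[0]:
            best = (key, float(c), m)
    roc.cutoff = best[1]
    roc.metrics = best[2]
    return roc
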