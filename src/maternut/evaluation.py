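"""Classifier diagnostics for the fitted outcome model and ITE summaries.

Diagnostics are computed on held-out factual predictions only (the
model is evaluated out-of-sample): the empirical ROC curve, its area
(equal to the Mann-Whitney concordance probability), and an operating
cutoff chosen by Youden's J = sensitivity + specificity - 1 with the
convention ``score >= cutoff`` predicts positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class RocCurve:
    """Empirical ROC over all distinct score thresholds."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float


def roc_auc(y_true, scores) -> RocCurve:
    """ROC curve with trapezoidal AUC and a Youden-selected cutoff."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("y_true and scores must align")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    fpr, tpr, thresholds = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    cutoff, sens, spec = select_cutoff(y, s)
    # drop sklearn's synthetic anchor threshold (inf above the max score)
    finite = np.isfinite(thresholds)
    return RocCurve(thresholds=thresholds[finite], fpr=fpr[finite],
                    tpr=tpr[finite], auc=auc, cutoff=cutoff,
                    sensitivity=sens, specificity=spec)


def select_cutoff(y_true, scores) -> tuple[float, float, float]:
    """Cutoff maximising Youden's J; ties break towards the lower cutoff.

    Returns ``(cutoff, sensitivity, specificity)`` with sensitivity and
    specificity evaluated at ``score >= cutoff => predicted positive``.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    best = None
    for c in np.unique(s):
        pred = s >= c
        sens = float((pred & (y == 1)).sum()) / n_pos
        spec = float((~pred & (y == 0)).sum()) / n_neg
        j = sens + spec - 1.0
        # strictly-better J wins; on a tie the lower cutoff is kept
        if best is None or j > best[0] + 1e-15:
            best = (j, float(c), sens, spec)
    _, cutoff, sens, spec = best
    return cutoff, sens, spec


@dataclass
class IteSummary:
    """Histogram and distributional summary of individual effects."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float
    quantiles: dict[float, float]


def summarize_ite(theta, bins: int = 30) -> IteSummary:
    """Bin counts (summing to n) plus mean, SD and standard quantiles."""
    t = np.asarray(theta, dtype=float)
    if t.size == 0:
        raise ValueError("empty ITE vector")
    counts, edges = np.histogram(t, bins=bins)
    qs = (2.5, 25.0, 50.0, 75.0, 97.5)
    quantiles = {q: float(np.percentile(t, q)) for q in qs}
    return IteSummary(bin_edges=edges, counts=counts,
                      mean=float(t.mean()), sd=float(t.std(ddof=0)),
                      quantiles=quantiles)
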