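"""Evaluation metrics: concordance index, MSE, rm², AUPR and multi-scale
binding-region hit accuracy."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score

__all__ = [
    "MetricsReport", "UndefinedMetricError", "concordance_index", "mse",
    "rm2_index", "binarize_and_aupr", "br_hit_accuracy", "evaluate_affinity",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value on the given inputs."""


@dataclass
class MetricsReport:
    ci: float
    mse: float
    rm2: float
    aupr: float | None = None
    br_accuracy: dict[int, float] = field(default_factory=dict)


def mse(preds, labels) -> float:
    preds = np.asarray(preds, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if preds.size == 0:
        raise UndefinedMetricError("MSE of empty input")
    return float(np.mean((preds - labels) ** 2))


def concordance_index(preds, labels) -> float:
    """Fraction of label-ordered pairs ranked concordantly; prediction ties
    score one half, label ties contribute no pair.

    Vectorized O(n log n) via sorting + cumulative counts on rank-compressed
    predictions.
    """
    preds = np.asarray(preds, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if preds.shape != labels.shape or preds.ndim != 1:
        raise ValueError("preds and labels must be equal-length vectors")
    n = len(preds)
    if n < 2:
        raise UndefinedMetricError("need at least two samples")
    order = np.argsort(labels, kind="stable")
    labels_s = labels[order]
    # rank-compress predictions
    pr = np.unique(preds, return_inverse=True)[1][order]
    m = pr.max() + 1
    total_pairs = 0
    concordant = 0.0
    below = np.zeros(m)  # counts of prediction ranks among strictly-smaller labels
    cum = 0
    i = 0
    while i < n:
        j = i
        while j < n and labels_s[j] == labels_s[i]:
            j += 1
        # samples [i, j) share a label; compare against all with smaller label
        if cum:
            cb = np.cumsum(below)
            for k in range(i, j):
                r = pr[k]
                smaller = cb[r - 1] if r > 0 else 0.0
                ties = below[r]
                concordant += smaller + 0.5 * ties
            total_pairs += (j - i) * cum
        for k in range(i, j):
            below[pr[k]] += 1
        cum += j - i
        i = j
    if total_pairs == 0:
        raise UndefinedMetricError("no strictly ordered label pair")
    return float(concordant / total_pairs)


def rm2_index(preds, labels) -> float:
    """``r² (1 − sqrt(r² − r0²))`` with r² the squared Pearson correlation and
    r0² the coefficient of determination of the zero-intercept regression of
    the labels on the predictions."""
    preds = np.asarray(preds, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if len(preds) < 3:
        raise UndefinedMetricError("need at least three samples")
    if np.std(preds) == 0 or np.std(labels) == 0:
        raise UndefinedMetricError("degenerate variance")
    r = np.corrcoef(preds, labels)[0, 1]
    r2 = r * r
    k = float(np.sum(preds * labels) / np.sum(preds * preds))
    ss_res = float(np.sum((labels - k * preds) ** 2))
    ss_tot = float(np.sum((labels - labels.mean()) ** 2))
    r02 = 1.0 - ss_res / ss_tot
    gap = max(r2 - r02, 0.0)
    return float(r2 * (1.0 - np.sqrt(gap)))


def binarize_and_aupr(preds, labels, threshold: float,
                      direction: str = "greater") -> float:
    """Area under the precision–recall curve after binarizing the labels.

    ``direction='greater'`` marks ``label > threshold`` positive (pKd-style);
    ``'geq'`` marks ``label >= threshold`` positive (KIBA-style).
    """
    preds = np.asarray(preds, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if direction == "greater":
        binary = labels > threshold
    elif direction == "geq":
        binary = labels >= threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if binary.all() or not binary.any():
        raise UndefinedMetricError("only one class after binarization")
    return float(average_precision_score(binary, preds))


def br_hit_accuracy(regions: Sequence[tuple[int, int]],
                    sites: Sequence[Sequence[tuple[int, int]]]) -> float:
    """Fraction of pairs whose predicted interval contains at least one
    annotated site residue. Pairs with no annotation are excluded."""
    hits = 0
    evaluated = 0
    for (start, end), true_sites in zip(regions, sites, strict=True):
        if not true_sites:
            continue
        evaluated += 1
        if any(s < end and e > start for s, e in true_sites):
            hits += 1
    if evaluated == 0:
        raise UndefinedMetricError("no annotated pair to evaluate")
    return hits / evaluated


def evaluate_affinity(preds, labels, aupr_threshold: float | None = None,
                      aupr_direction: str = "greater") -> MetricsReport:
    aupr = None
    if aupr_threshold is not None:
        try:
            aupr = binarize_and_aupr(preds, labels, aupr_threshold,
                                     aupr_direction)
        except UndefinedMetricError:
            aupr = None
    return MetricsReport(ci=concordance_index(preds, labels),
                         mse=mse(preds, labels),
                         rm2=rm2_index(preds, labels),
                         aupr=aupr)
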