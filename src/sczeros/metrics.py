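"""Evaluation metrics and rank aggregation for the zero-injection benchmark."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score, silhouette_samples

__all__ = [
    "adjusted_rand_index",
    "precision_recall_f1",
    "average_silhouette",
    "weighted_rank_average",
    "rank_with_ties",
]


def adjusted_rand_index(labels_true, labels_pred) -> float:
    """Chance-corrected pair-counting agreement of two partitions.

    1 for identical partitions (up to label renaming); around 0 for random
    agreement. In the degenerate case where the expected index equals the
    maximum index (e.g., both partitions are one cluster), returns 1 for
    identical partitions and 0 otherwise.
    """
    a = np.asarray(labels_true)
    b = np.asarray(labels_pred)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))


def precision_recall_f1(discovered, truth) -> tuple[float, float, float]:
    """Precision, recall, and F1 of boolean discoveries against truth.

    Conventions: if truth and discoveries are both empty all three are 1;
    if truth has positives but TP = 0 (including no discoveries) all three
    are 0.
    """
    d = np.asarray(discovered, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if d.shape != t.shape:
        raise ValueError("discovered and truth must have equal length")
    tp = int(np.sum(d & t))
    fp = int(np.sum(d & ~t))
    fn = int(np.sum(~d & t))
    if tp == 0:
        if fp == 0 and fn == 0:
            return 1.0, 1.0, 1.0
        return 0.0, 0.0, 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def average_silhouette(coords_2d, labels) -> float:
    """Mean silhouette of known labels in the 2-D embedding.

    Per point: (b - a) / max(a, b) with Euclidean distance, where a is the
    mean within-label distance and b the smallest mean distance to another
    label; points in singleton labels contribute 0.
    """
    coords = np.asarray(coords_2d, dtype=float)
    labels = np.asarray(labels)
    if coords.ndim != 2 or coords.shape[0] != labels.size:
        raise ValueError("coords_2d must be n x d matching labels")
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 points")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct labels")
    if np.any(counts == 1):
        # silhouette_samples rejects singleton clusters; score them 0 by hand
        vals = np.zeros(labels.size)
        ok = np.isin(labels, uniq[counts > 1])
        sub_labels = labels[ok]
        if np.unique(sub_labels).size >= 2:
            vals[ok] = silhouette_samples(coords[ok], sub_labels)
        return float(vals.mean())
    return float(silhouette_samples(coords, labels).mean())


def rank_with_ties(values, higher_is_better: bool = True) -> np.ndarray:
    """Competition-free ranks (1 = best), ties receiving the average rank."""
    v = np.asarray(values, dtype=float)
    return rankdata(-v if higher_is_better else v, method="average")


def weighted_rank_average(ranks, weights) -> np.ndarray:
    """Weighted arithmetic mean of ranks across conditions.

    ``ranks`` is a conditions x input-types matrix (each row already ranked,
    ties as average ranks); ``weights`` is one non-negative weight per
    condition, not all zero.
    """
    r = np.asarray(ranks, dtype=float)
    w = np.asarray(weights, dtype=float)
    if r.ndim != 2:
        raise ValueError("ranks must be a 2-D matrix")
    if w.ndim != 1 or w.size != r.shape[0]:
        raise ValueError("weights must have one entry per condition (row)")
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    return (w @ r) / w.sum()
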