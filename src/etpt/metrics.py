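"""Partition-comparison and cluster-validity metrics.

CCR (correct classification rate) scores a predicted partition against a
reference by the best one-to-one matching of cluster labels, found by the
Hungarian algorithm on the confusion matrix.  The adjusted Rand index is the
Hubert–Arabie chance-corrected pair-counting agreement.  The Dunn index is an
internal validity measure: minimum single-linkage between-cluster separation
over maximum cluster diameter, here measured with the L1 distance on the log
e-TPT upper boundaries — the same geometry the clustering itself optimises.
Variation of information is Meila's entropy metric between two partitions
(natural log); it is a distance, so lower means more similar.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist
from scipy.stats import entropy
from sklearn.metrics import adjusted_rand_score, mutual_info_score

__all__ = ["ccr", "adjusted_rand", "dunn_index", "variation_of_information",
           "confusion_matrix", "match_labels"]


def _canonical(labels) -> np.ndarray:
    labels = np.asarray(labels).ravel()
    _, inv = np.unique(labels, return_inverse=True)
    return inv


def _check_same_n(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"partitions have different sizes ({a.shape[0]} vs {b.shape[0]})")


def confusion_matrix(a, b) -> np.ndarray:
    """Contingency table of two label vectors (rows: a, cols: b)."""
    a, b = _canonical(a), _canonical(b)
    _check_same_n(a, b)
    table = np.zeros((a.max() + 1, b.max() + 1), dtype=int)
    np.add.at(table, (a, b), 1)
    return table


def match_labels(predicted, truth) -> dict[int, int]:
    """Optimal bijection predicted-cluster -> true-cluster (maximal agreement)."""
    table = confusion_matrix(predicted, truth)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return dict(zip(rows.tolist(), cols.tolist()))


def ccr(predicted, truth) -> float:
    """Correct classification rate: best-bijection agreement in [0, 1]."""
    table = confusion_matrix(predicted, truth)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum() / table.sum())


def adjusted_rand(a, b) -> float:
    """Hubert–Arabie adjusted Rand index (expected 0 under chance, max 1)."""
    a, b = _canonical(a), _canonical(b)
    _check_same_n(a, b)
    return float(adjusted_rand_score(a, b))


def dunn_index(points: np.ndarray, labels) -> float:
    """Minimum between-cluster separation / maximum cluster diameter (L1).

    ``points`` is the (N, T) matrix the clustering was run on, typically log
    e-TPT upper boundaries.  Separation is single-linkage; diameter is the
    largest within-cluster pairwise distance.  Requires at least two clusters
    and a strictly positive maximum diameter.
    """
    points = np.asarray(points, dtype=float)
    labels = _canonical(labels)
    k = labels.max() + 1
    if k < 2:
        raise ValueError("Dunn index needs at least two clusters")
    groups = [points[labels == c] for c in range(k)]
    max_diam = 0.0
    for g in groups:
        if len(g) > 1:
            max_diam = max(max_diam, float(pdist(g, metric="cityblock").max()))
    if max_diam == 0.0:
        raise ValueError("all clusters are singletons or degenerate (zero diameter)")
    min_sep = np.inf
    for i in range(k):
        for j in range(i + 1, k):
            min_sep = min(min_sep, float(cdist(groups[i], groups[j], metric="cityblock").min()))
    return min_sep / max_diam


def variation_of_information(a, b) -> float:
    """VI = H(a) + H(b) - 2 I(a; b), natural log; 0 iff the partitions agree."""
    a, b = _canonical(a), _canonical(b)
    _check_same_n(a, b)
    h_a = entropy(np.bincount(a))
    h_b = entropy(np.bincount(b))
    vi = h_a + h_b - 2.0 * mutual_info_score(a, b)
    return float(max(vi, 0.0))
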