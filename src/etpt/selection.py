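"""Choosing the pen thickness (cross-validation) and the number of clusters
(gap statistic).

Thickness selection assumes known group labels (the simulation setting): for
each candidate thickness, a stratified five-fold split trains K-medians on
the training folds' log e-TPT upper boundaries, matches trained clusters to
the true groups by optimal assignment on the training confusion matrix, and
scores the held-out fold by nearest-prototype misclassification.  The
thickness with the smallest mean CV error wins; ties go to the smallest
thickness.  With unknown truth, an internal index such as Dunn
(:func:`etpt.metrics.dunn_index`) is the fallback.

The number of clusters uses the gap statistic of Tibshirani, Walther &
Hastie: compare log within-cluster dispersion (the same L1 cost the
clustering minimises) against its expectation under B reference datasets
drawn uniformly over each column's observed range, and pick the smallest k
whose gap is within one standard error of the next one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cluster import assign_step, cost, kmedians
from .io import TimeSeriesSet
from .metrics import match_labels
from .pen import log_upper_boundaries

__all__ = ["CVResult", "predict_labels", "cv_thickness", "gap_statistic_k"]


@dataclass
class CVResult:
    """Per-thickness cross-validated misclassification and the selected value."""

    thickness_grid: list[int]
    cv_error: dict[int, float]
    selected: int
    fold_assignments: np.ndarray
    n_folds: int


def predict_labels(test_logb: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    """Nearest-prototype (L1) labels for held-out log-boundary rows."""
    test_logb = np.atleast_2d(np.asarray(test_logb, dtype=float))
    prototypes = np.atleast_2d(np.asarray(prototypes, dtype=float))
    if test_logb.shape[1] != prototypes.shape[1]:
        raise ValueError(
            f"series length {test_logb.shape[1]} does not match prototype "
            f"length {prototypes.shape[1]}"
        )
    return assign_step(test_logb, prototypes)


def cv_thickness(
    data: TimeSeriesSet,
    true_labels: np.ndarray,
    thickness_grid,
    k: int,
    n_folds: int = 5,
    gamma: float = 0.1,
    n_restarts: int = 10,
    seed: int | None = None,
) -> CVResult:
    """Select the pen thickness by stratified K-fold CV against known labels.

    Stratifying the folds by true group keeps every group represented in
    every training set, which the cluster-to-truth matching requires.
    """
    grid = sorted(int(t) for t in thickness_grid)
    if not grid:
        raise ValueError("thickness grid is empty")
    truth = np.asarray(true_labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(truth)), truth))
    fold_of = np.empty(len(truth), dtype=int)
    for f, (_, test_idx) in enumerate(folds):
        fold_of[test_idx] = f

    rng = np.random.default_rng(seed)
    errors: dict[int, float] = {}
    for tau in grid:
        logb = log_upper_boundaries(data, tau, gamma)
        fold_errs = []
        for train_idx, test_idx in folds:
            fit = kmedians(logb[train_idx], k, n_restarts=n_restarts,
                           rng=rng)
            mapping = match_labels(fit.labels, truth[train_idx])
            pred = predict_labels(logb[test_idx], fit.prototypes)
            pred_true = np.array([mapping.get(c, -1) for c in pred])
            fold_errs.append(float(np.mean(pred_true != truth[test_idx])))
        errors[tau] = float(np.mean(fold_errs))
    selected = min(grid, key=lambda tau: (errors[tau], tau))
    return CVResult(grid, errors, selected, fold_of, n_folds)


def gap_statistic_k(
    logb: np.ndarray,
    k_max: int = 6,
    b_refs: int = 50,
    seed: int | None = None,
    n_restarts: int = 10,
) -> int:
    """Number of clusters by the gap statistic with a uniform reference.

    Dispersion W_k is the L1 K-medians cost; references draw each column
    uniformly over its observed range.  Returns the smallest k with
    ``Gap(k) >= Gap(k+1) - s_{k+1}`` (1-SE rule), or ``k_max`` if none
    qualifies.  All-identical rows short-circuit to 1.
    """
    logb = np.asarray(logb, dtype=float)
    if np.allclose(logb, logb[0]):
        return 1
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    rng = np.random.default_rng(seed)
    n, t_len = logb.shape
    tiny = np.finfo(float).tiny

    # Reference box aligned with the data's principal axes: e-TPT envelopes
    # are strongly autocorrelated over time, and an axis-aligned uniform box
    # would not reproduce that correlation structure.
    center = logb.mean(axis=0)
    _, _, vt = np.linalg.svd(logb - center, full_matrices=False)
    rotated = (logb - center) @ vt.T
    lo, hi = rotated.min(axis=0), rotated.max(axis=0)

    def dispersion(mat: np.ndarray, k: int) -> float:
        fit = kmedians(mat, k, n_restarts=n_restarts, rng=rng)
        return max(fit.final_cost, tiny)

    ks = np.arange(1, k_max + 1)
    log_w = np.array([np.log(dispersion(logb, k)) for k in ks])
    log_w_ref = np.empty((b_refs, len(ks)))
    for b in range(b_refs):
        ref = rng.uniform(lo, hi, size=(n, rotated.shape[1])) @ vt + center
        log_w_ref[b] = [np.log(dispersion(ref, k)) for k in ks]
    gap = log_w_ref.mean(axis=0) - log_w
    s = log_w_ref.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / b_refs)
    # smallest k whose gap comes within one standard error of the global
    # maximum (the "globalSEmax" rule): robust to the flat stretch before
    # structure appears, where the sequential first-decrease rule can stop
    # at k=1 on clearly clustered data
    j_max = int(np.argmax(gap))
    for j in range(len(ks)):
        if gap[j] >= gap[j_max] - s[j_max]:
            return int(ks[j])
    return int(k_max)
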