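"""K-medians clustering of log e-TPT upper boundaries.

Maximising the product over series of the per-series geometric-mean TPMA0
similarity to its cluster prototype is equivalent to minimising

    W(P, M) = sum_t sum_i | log U^E(X_i(t)) - mu_{c_i}(t) |,

an L1 problem on the matrix ``logb[i, t] = log U^E(X_i(t))``.  K-medians
solves it by alternating nearest-prototype assignment (cityblock distance)
with coordinate-wise median updates; both steps are non-increasing in W, so
the cost trace is monotone and the algorithm terminates when labels stop
changing.  Prototypes live in the log-boundary space; no attempt is made to
invert them back to a concrete time series (the inverse is not unique, and
the algorithm never needs it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["ClusteringResult", "cost", "assign_step", "update_step", "kmedians",
           "geometric_mean_objective"]


@dataclass
class ClusteringResult:
    """Outcome of one best-of-restarts K-medians run.

    ``labels`` are 0-based cluster indices; ``prototypes`` is the (K, T)
    matrix of per-cluster coordinate-wise medians in log-boundary space;
    ``cost_trace`` is the per-iteration cost of the winning restart.
    """

    labels: np.ndarray
    prototypes: np.ndarray
    cost_trace: list[float]
    k: int
    seed: int | None = None
    n_restarts: int = 1
    final_cost: float = field(init=False)

    def __post_init__(self) -> None:
        self.final_cost = float(self.cost_trace[-1])


def _check_logb(logb: np.ndarray) -> np.ndarray:
    logb = np.asarray(logb, dtype=float)
    if logb.ndim != 2:
        raise ValueError("log-boundary matrix must be 2-D (N, T)")
    if not np.all(np.isfinite(logb)):
        raise ValueError("log-boundary matrix must be finite; use gamma > 0")
    return logb


def cost(logb: np.ndarray, labels: np.ndarray, prototypes: np.ndarray) -> float:
    """Total L1 deviation of each row from its cluster prototype."""
    logb = _check_logb(logb)
    labels = np.asarray(labels)
    prototypes = np.atleast_2d(np.asarray(prototypes, dtype=float))
    k = prototypes.shape[0]
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in 0..{k - 1}")
    return float(np.abs(logb - prototypes[labels]).sum())


def assign_step(logb: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    """Assign each row to the L1-nearest prototype; ties go to the lowest index."""
    d = cdist(np.asarray(logb, dtype=float),
              np.atleast_2d(np.asarray(prototypes, dtype=float)),
              metric="cityblock")
    return np.argmin(d, axis=1)


def update_step(logb: np.ndarray, labels: np.ndarray, k: int,
                prototypes: np.ndarray | None = None) -> np.ndarray:
    """Coordinate-wise median of each cluster's rows.

    An empty cluster is repaired by re-seeding its prototype with the row
    farthest (L1) from the cluster's current prototype, keeping K fixed.
    For even cluster sizes the median is the midpoint of the two central
    values (numpy convention), which is L1-optimal.
    """
    logb = np.asarray(logb, dtype=float)
    labels = np.asarray(labels)
    new = np.empty((k, logb.shape[1]))
    for c in range(k):
        members = logb[labels == c]
        if len(members):
            new[c] = np.median(members, axis=0)
        else:
            if prototypes is None:
                raise ValueError(f"cluster {c} is empty and no prototype given to repair it")
            d = np.abs(logb - prototypes[c]).sum(axis=1)
            new[c] = logb[np.argmax(d)]
    return new


def kmedians(
    logb: np.ndarray,
    k: int,
    n_restarts: int = 10,
    max_iter: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ClusteringResult:
    """Best-of-restarts K-medians on a log-boundary matrix.

    Each restart seeds prototypes with K distinct rows drawn uniformly at
    random, then alternates assignment and median updates until the labels
    stabilise or ``max_iter`` is reached; the restart with the lowest final
    cost wins.  Deterministic given ``seed``.
    """
    logb = _check_logb(logb)
    n = logb.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if rng is None:
        rng = np.random.default_rng(seed)

    best: ClusteringResult | None = None
    for _ in range(n_restarts):
        prototypes = logb[rng.choice(n, size=k, replace=False)].copy()
        labels = assign_step(logb, prototypes)
        trace = [cost(logb, labels, prototypes)]
        for _ in range(max_iter):
            prototypes = update_step(logb, labels, k, prototypes)
            new_labels = assign_step(logb, prototypes)
            trace.append(cost(logb, new_labels, prototypes))
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        result = ClusteringResult(labels, prototypes, trace, k,
                                  seed=seed, n_restarts=n_restarts)
        if best is None or result.final_cost < best.final_cost:
            best = result
    assert best is not None
    return best


def geometric_mean_objective(logb: np.ndarray, labels: np.ndarray,
                             prototypes: np.ndarray) -> float:
    """Summed log geometric-mean TPMA0 similarity of rows to their prototypes.

    Equals ``-cost(logb, labels, prototypes) / T``; exposed so the
    equivalence between similarity maximisation and L1 minimisation can be
    checked numerically on any result.
    """
    logb = np.asarray(logb, dtype=float)
    prototypes = np.atleast_2d(prototypes)
    t_len = logb.shape[1]
    log_eta = -np.abs(logb - prototypes[np.asarray(labels)])
    return float(log_eta.sum() / t_len)
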