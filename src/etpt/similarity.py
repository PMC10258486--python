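"""Thick-pen measures of association: TPMA and its zero-inflation variant TPMA0.

TPMA compares two series through the overlap of their pen areas at each time:
the ratio of the intersection of the boundary intervals to their union, a
number in (-1, 1] that is positive exactly when the intervals overlap.

For nonnegative zero-inflated series the lower boundary is pinned at zero and
only the ensemble upper boundaries matter, giving TPMA0 = min(U_x, U_y) /
max(U_x, U_y) in (0, 1].  Its log obeys
``log eta(t) = -|log U_x(t) - log U_y(t)|``, which is the identity that turns
similarity maximisation into an L1 problem on log upper boundaries.

Both measures assume the two series are on approximately the same scale; no
rescaling is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io import TimeSeriesSet
from .pen import BoundarySet, PenConfig, transform_set

__all__ = [
    "SimilarityProfile",
    "tpma",
    "tpma0",
    "aggregate_similarity",
    "pairwise_similarity",
]


@dataclass
class SimilarityProfile:
    """Per-time similarity values between two series at one pen thickness."""

    values: np.ndarray
    measure: Literal["TPMA", "TPMA0"]
    thickness: int


def _row(bounds, which: str, index: int = 0) -> np.ndarray:
    arr = getattr(bounds, which)
    return np.atleast_2d(arr)[index]


def tpma(bounds_x: BoundarySet, bounds_y: BoundarySet, row_x: int = 0, row_y: int = 0) -> SimilarityProfile:
    """Thick-pen measure of association between two boundary rows.

    ``rho(t) = [min(U_x, U_y) - max(L_x, L_y)] / [max(U_x, U_y) - min(L_x, L_y)]``
    """
    if bounds_x.pen != bounds_y.pen:
        raise ValueError("boundary sets were computed with different pens")
    ux, lx = _row(bounds_x, "upper", row_x), _row(bounds_x, "lower", row_x)
    uy, ly = _row(bounds_y, "upper", row_y), _row(bounds_y, "lower", row_y)
    if ux.shape != uy.shape:
        raise ValueError("series lengths differ")
    num = np.minimum(ux, uy) - np.maximum(lx, ly)
    den = np.maximum(ux, uy) - np.minimum(lx, ly)
    if np.any(den <= 0):
        raise ValueError("degenerate boundaries: zero union span at some time point")
    return SimilarityProfile(num / den, "TPMA", bounds_x.pen.thickness)


def tpma0(upper_x: np.ndarray, upper_y: np.ndarray, thickness: int = 0) -> SimilarityProfile:
    """Zero-inflation-adapted TPMA from two ensemble upper boundaries.

    ``eta(t) = min(U_x, U_y) / max(U_x, U_y)`` in (0, 1]; symmetric and
    invariant to a common positive rescaling of both boundaries.
    """
    ux = np.asarray(upper_x, dtype=float).ravel()
    uy = np.asarray(upper_y, dtype=float).ravel()
    if ux.shape != uy.shape:
        raise ValueError("series lengths differ")
    if np.any(ux <= 0) or np.any(uy <= 0):
        raise ValueError(
            "upper boundaries must be strictly positive; use a pen with gamma > 0"
        )
    return SimilarityProfile(np.minimum(ux, uy) / np.maximum(ux, uy), "TPMA0", thickness)


def aggregate_similarity(profile: SimilarityProfile) -> float:
    """Geometric mean over time of a strictly positive similarity profile."""
    vals = np.asarray(profile.values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty similarity profile")
    if np.any(vals <= 0):
        raise ValueError(
            "geometric mean requires strictly positive values; "
            "TPMA profiles may be nonpositive — use TPMA0"
        )
    return float(np.exp(np.mean(np.log(vals))))


def pairwise_similarity(data: TimeSeriesSet, thickness: int, gamma: float = 0.1) -> np.ndarray:
    """N x N matrix of aggregate TPMA0 similarities at one pen thickness."""
    bounds = transform_set(data, PenConfig("square", thickness, gamma), ensemble=True)
    logu = np.log(bounds.upper)
    n = logu.shape[0]
    sim = np.ones((n, n))
    for i in range(n):
        d = np.mean(np.abs(logu[i] - logu[i + 1:]), axis=1)  # -log geometric mean
        sim[i, i + 1:] = sim[i + 1:, i] = np.exp(-d)
    return sim
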