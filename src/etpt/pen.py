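"""Thick-pen transform (TPT) and ensemble thick-pen transform (e-TPT).

The thick-pen transform traces a time series with a pen of thickness ``tau``
and records, at every time point, the upper and lower boundary of the inked
area.  A square pen takes windowed extremes and pads them by ``(tau/2)*gamma``;
a round pen adds a semicircular offset ``gamma*sqrt(tau^2/4 - k^2)`` inside the
extreme.  Small thicknesses track local features, large thicknesses the global
trend, which is what makes the transform a multiscale summary.

The ensemble variant (square pen only) averages the ``tau+1`` windowed extremes
obtained by shifting the window's starting point, giving a smoother envelope
that is less sensitive to single outlying observations.  For nonnegative
zero-inflated series with ``gamma > 0`` the ensemble upper boundary is bounded
below by ``(tau/2)*gamma > 0``, which is what later allows taking logarithms.

Windows overrunning the ends of the series are truncated to the observed
range; every window still contains its centre point, so no window is empty on
fully observed data.  Missing values are simply excluded from the extremes; a
window in which every point is missing raises an error rather than imputing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import TimeSeriesSet

__all__ = [
    "PenConfig",
    "BoundarySet",
    "EnsembleBoundarySet",
    "tpt_boundaries",
    "etpt_boundaries",
    "transform_set",
    "log_upper_boundaries",
]

DEFAULT_GAMMA = 0.1


@dataclass(frozen=True)
class PenConfig:
    """Pen shape, thickness and scaling factor.

    ``gamma`` rescales the pen thickness to the data's units; the conventional
    default is 0.1.
    """

    shape: Literal["square", "round"] = "square"
    thickness: int = 10
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if self.shape not in ("square", "round"):
            raise ValueError(f"unknown pen shape {self.shape!r}")
        if int(self.thickness) != self.thickness or self.thickness < 1:
            raise ValueError("thickness must be a positive integer")
        object.__setattr__(self, "thickness", int(self.thickness))
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


@dataclass
class BoundarySet:
    """Classic TPT boundaries for a batch of series (rows)."""

    upper: np.ndarray
    lower: np.ndarray
    pen: PenConfig


@dataclass
class EnsembleBoundarySet:
    """e-TPT boundaries for a batch of series (rows); square pen only."""

    upper: np.ndarray
    lower: np.ndarray
    pen: PenConfig


def _as_masked_rows(series: np.ndarray, missing: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    x = np.atleast_2d(np.asarray(series, dtype=float))
    if missing is None:
        mask = np.isnan(x)
    else:
        mask = np.atleast_2d(np.asarray(missing, dtype=bool)) | np.isnan(x)
    if np.any(x[~mask] < 0):
        raise ValueError("series values must be nonnegative")
    return x, mask


def _sliding_extreme(x: np.ndarray, mask: np.ndarray, width: int, kind: str) -> np.ndarray:
    """Extremes of all width-`width` windows, truncated at the edges.

    Returns an (N, T + width - 1) array whose column j is the extreme of the
    window starting at position j - (width - 1) (clipped to [0, T-1]).
    Fully-missing windows come out as +/-inf and are caught by the caller.
    """
    fill = -np.inf if kind == "max" else np.inf
    xp = np.where(mask, fill, x)
    pad = np.full((x.shape[0], width - 1), fill)
    xp = np.concatenate([pad, xp, pad], axis=1)
    win = sliding_window_view(xp, width, axis=1)
    return win.max(axis=2) if kind == "max" else win.min(axis=2)


def _window_bounds(tau: int) -> tuple[int, int]:
    # k ranges over [-tau/2, tau/2] ∩ Z
    return math.ceil(-tau / 2), math.floor(tau / 2)


def tpt_boundaries(
    series: np.ndarray,
    pen: PenConfig,
    missing: np.ndarray | None = None,
) -> BoundarySet:
    """Classic thick-pen boundaries of one series or a batch (rows).

    For a square pen, ``U(t) = max_k X(t+k) + (tau/2)*gamma`` with
    ``k in [-tau/2, tau/2] ∩ Z``, and symmetrically for ``L`` with min/minus.
    The round pen moves the gamma term inside the extreme as a semicircular
    offset.  Windows are truncated at the series ends.
    """
    x, mask = _as_masked_rows(series, missing)
    tau, gamma = pen.thickness, pen.gamma
    lo, hi = _window_bounds(tau)
    width = hi - lo + 1
    t_len = x.shape[1]
    # window of t starts at t+lo, i.e. column t+lo+(width-1) = t+hi of the
    # padded sliding-extreme array
    cols = np.arange(t_len) + hi

    if pen.shape == "square":
        upper = _sliding_extreme(x, mask, width, "max")[:, cols] + (tau / 2) * gamma
        lower = _sliding_extreme(x, mask, width, "min")[:, cols] - (tau / 2) * gamma
    else:  # round pen: offset depends on k, evaluate per shift
        ks = np.arange(lo, hi + 1)
        offsets = gamma * np.sqrt(np.maximum(tau**2 / 4 - ks.astype(float) ** 2, 0.0))
        n = x.shape[0]
        upper = np.full((n, t_len), -np.inf)
        lower = np.full((n, t_len), np.inf)
        xu = np.where(mask, -np.inf, x)
        xl = np.where(mask, np.inf, x)
        for k, off in zip(ks, offsets):
            src = slice(min(max(0, k), t_len), max(0, min(t_len, t_len + k)))
            dst = slice(min(max(0, -k), t_len), max(0, min(t_len, t_len - k)))
            upper[:, dst] = np.maximum(upper[:, dst], xu[:, src] + off)
            lower[:, dst] = np.minimum(lower[:, dst], xl[:, src] - off)

    if not (np.all(np.isfinite(upper)) and np.all(np.isfinite(lower))):
        raise ValueError(
            "a pen window contains no observed value; gap too wide for "
            f"thickness {tau}"
        )
    return BoundarySet(upper, lower, pen)


def etpt_boundaries(
    series: np.ndarray,
    pen: PenConfig,
    missing: np.ndarray | None = None,
) -> EnsembleBoundarySet:
    """Ensemble thick-pen boundaries of one series or a batch (rows).

    ``U^E(t)`` averages, over the shift ``l = 0..tau``, the maxima of the
    windows ``[t-l, t+tau-l]`` (truncated to the series), then adds
    ``(tau/2)*gamma``; ``L^E`` mirrors it with minima and subtraction.
    Defined for square pens only.
    """
    if pen.shape != "square":
        raise ValueError("the ensemble transform is defined for square pens only")
    x, mask = _as_masked_rows(series, missing)
    tau, gamma = pen.thickness, pen.gamma
    width = tau + 1
    t_len = x.shape[1]

    def ensemble(kind: str) -> np.ndarray:
        ext = _sliding_extreme(x, mask, width, kind)
        # column j holds the window starting at j-tau; U^E(t) averages windows
        # starting at t-tau .. t, i.e. columns t .. t+tau
        if not np.all(np.isfinite(ext[:, : t_len + tau])):
            raise ValueError(
                "a pen window contains no observed value; gap too wide for "
                f"thickness {tau}"
            )
        win = sliding_window_view(ext[:, : t_len + tau], width, axis=1)
        return win.mean(axis=2)

    upper = ensemble("max") + (tau / 2) * gamma
    lower = ensemble("min") - (tau / 2) * gamma
    return EnsembleBoundarySet(upper, lower, pen)


def transform_set(
    data: TimeSeriesSet,
    pen: PenConfig,
    ensemble: bool = True,
) -> BoundarySet | EnsembleBoundarySet:
    """Apply the (e-)TPT to every series in a :class:`TimeSeriesSet`."""
    fn = etpt_boundaries if ensemble else tpt_boundaries
    return fn(data.values, pen, missing=data.missing_mask)


def log_upper_boundaries(data: TimeSeriesSet, thickness: int, gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """``log U^E`` matrix used as the clustering feature space.

    Requires ``gamma > 0`` so that the ensemble upper boundary is bounded away
    from zero on zero-inflated data.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive to take logarithms of upper boundaries")
    pen = PenConfig("square", thickness, gamma)
    bounds = transform_set(data, pen, ensemble=True)
    return np.log(bounds.upper)
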