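"""Time-series container and CSV/TSV matrix I/O.

The universal input is a set of N nonnegative, equal-length series stored
rows-are-series.  On disk this is a wide CSV/TSV: first column the series id,
remaining columns the time points; empty cells or ``NA`` mark missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TimeSeriesSet", "read_matrix", "write_matrix"]


@dataclass
class TimeSeriesSet:
    """N equal-length nonnegative time series.

    Parameters
    ----------
    values : (N, T) float array
        Observed values; entries under ``missing_mask`` are ignored.
    series_ids : sequence of str, optional
        Row labels; defaults to ``s0..s{N-1}``.
    time_index : sequence, optional
        Column labels; defaults to ``1..T``.
    missing_mask : (N, T) bool array, optional
        True marks an unobserved entry.
    """

    values: np.ndarray
    series_ids: Sequence[str] | None = None
    time_index: Sequence | None = None
    missing_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (N, T) array")
        n, t = self.values.shape
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (n, t):
                raise ValueError("missing_mask shape must match values")
            self.missing_mask = self.missing_mask | np.isnan(self.values)
        observed = self.values[~self.missing_mask]
        if observed.size and np.any(observed < 0):
            i, j = np.argwhere(~self.missing_mask & (self.values < 0))[0]
            raise ValueError(
                f"negative value {self.values[i, j]} at series {i}, time {j}; "
                "series must be nonnegative"
            )
        if self.series_ids is None:
            self.series_ids = [f"s{i}" for i in range(n)]
        else:
            self.series_ids = list(map(str, self.series_ids))
            if len(self.series_ids) != n:
                raise ValueError("series_ids length must equal N")
        if self.time_index is None:
            self.time_index = list(range(1, t + 1))
        else:
            self.time_index = list(self.time_index)
            if len(self.time_index) != t:
                raise ValueError("time_index length must equal T")

    @property
    def n_series(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=pd.Index(self.series_ids, name="id"),
                            columns=self.time_index)


def read_matrix(path: str | Path, sep: str | None = None) -> TimeSeriesSet:
    """Read a wide matrix (first column = series id) into a :class:`TimeSeriesSet`.

    The separator is sniffed from the extension (``.tsv`` → tab) unless given.
    Ragged rows and negative entries are rejected with the offending location.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or unreadable matrix file") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no time-point columns found")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    neg = np.argwhere(np.nan_to_num(values, nan=0.0) < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"{path}: negative value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return TimeSeriesSet(values, series_ids=df.index, time_index=df.columns)


def write_matrix(path: str | Path, data: TimeSeriesSet, sep: str | None = None) -> None:
    """Write a :class:`TimeSeriesSet` as a wide matrix; missing values become NA."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    data.to_frame().to_csv(path, sep=sep, na_rep="NA")
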