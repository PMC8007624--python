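"""The universal input container: a named multivariate time series.

Abundance tables are small (hundreds of rows, tens of species), so a plain
float ndarray plus a name list is the whole container; conversion to and
from :class:`pandas.DataFrame` covers interchange with file I/O and user
code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TimeSeriesSet:
    """Multivariate time series: rows are time points, columns are variables.

    Parameters
    ----------
    values
        Real matrix of shape (L, S); all entries must be finite.
    names
        Unique variable (species) labels, one per column.
    dt_label
        Optional annotation of the sampling interval (e.g. ``"2 weeks"``).
    """

    values: np.ndarray
    names: list[str]
    dt_label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (time x variables)")
        self.names = [str(n) for n in self.names]
        if len(self.names) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.names)} names for {self.values.shape[1]} columns"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("variable names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("all values must be finite")

    @property
    def length(self) -> int:
        """Number of retained time points (L)."""
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def series(self, name: str) -> np.ndarray:
        """Return one column by name (a view, not a copy)."""
        return self.values[:, self.names.index(name)]

    def window(self, start: int, stop: int) -> "TimeSeriesSet":
        """Sub-series for rows ``start:stop`` (half-open, 0-based)."""
        if not (0 <= start < stop <= self.length):
            raise ValueError(f"window [{start}, {stop}) outside series of length {self.length}")
        return TimeSeriesSet(self.values[start:stop].copy(), list(self.names), self.dt_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dt_label: str | None = None) -> "TimeSeriesSet":
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns], dt_label)


@dataclass
class GroundTruth:
    """Generator-side record of what a synthetic community really contains.

    Attributes
    ----------
    coupling
        The S x S directed coupling matrix B actually used; entry (i, j) is
        the strength with which species i drives species j.
    interacting
        Names of species with at least one coupling entry (row or column)
        of magnitude at or above ``threshold`` -- the planted "truly
        interacting" set recovery tests score against.
    threshold
        The magnitude cut used to define membership.
    """

    coupling: np.ndarray
    interacting: list[str]
    threshold: float = field(default=0.05)
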