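"""In-memory container for a hyper-temporal NDVI raster stack.

The stack is a dense (time, row, col) array on a strictly regular date
grid, with an explicit boolean missing mask — masked observations are
NaN in ``values`` but the mask, not the sentinel, is authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import GeoTransform

__all__ = ["NDVIStack"]


@dataclass
class NDVIStack:
    """Per-pixel NDVI time series on a regular time grid.

    Parameters
    ----------
    values : (T, R, C) float array, NaN at masked entries
    mask : (T, R, C) bool array, True = missing
    dates : DatetimeIndex of length T, strictly increasing, constant step
    transform : affine georeferencing of the (R, C) grid
    crs : coordinate-reference-system tag (opaque string)
    """

    values: np.ndarray
    mask: np.ndarray
    dates: pd.DatetimeIndex
    transform: GeoTransform = field(default_factory=lambda: GeoTransform.north_up(0.0, 0.0, 30.0))
    crs: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.dates = pd.DatetimeIndex(self.dates)
        if self.values.ndim != 3:
            raise ValueError("values must be a (time, row, col) array")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if len(self.dates) != self.values.shape[0]:
            raise ValueError("date index length does not match time axis")
        if len(self.dates) > 1:
            steps = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
            if (steps <= 0).any():
                raise ValueError("dates must be strictly increasing")
            if len(set(steps)) > 1:
                raise ValueError("dates must lie on a constant-step grid")

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_rows(self) -> int:
        return self.values.shape[1]

    @property
    def n_cols(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self):
        return self.values.shape

    @property
    def step_days(self) -> int:
        if len(self.dates) < 2:
            return 0
        return int((self.dates[1] - self.dates[0]).days)

    def series(self, row: int, col: int) -> np.ndarray:
        """The (masked-as-NaN) time series of one pixel."""
        return self.values[:, row, col]

    def copy(self) -> "NDVIStack":
        return NDVIStack(
            values=self.values.copy(),
            mask=self.mask.copy(),
            dates=self.dates.copy(),
            transform=self.transform,
            crs=self.crs,
        )
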