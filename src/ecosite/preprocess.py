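"""NDVI computation, gap infilling, and seasonal-trend filtering.

The preprocessing chain turns raw band or NDVI scenes into a complete,
noise-filtered series per pixel:

1. NDVI = (NIR - red) / (NIR + red) per scene,
2. linear-in-time infilling of QA gaps on a regular acquisition grid,
3. additive seasonal-trend decomposition (LOESS-based STL) into
   trend + seasonal + remainder,
4. recombination of trend and seasonal only, discarding the remainder,
   which carries residual sensor noise and unmodelled signal.

A 16-day grid with a 365.25-day year gives ~22.8 scenes per cycle; the
decomposition uses the nearest integer period (23 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd
from statsmodels.tsa.seasonal import STL

from .stack import NDVIStack

__all__ = [
    "SpectralBands",
    "Decomposition",
    "compute_ndvi",
    "build_time_grid",
    "infill_series",
    "decompose_series",
    "filter_series",
    "preprocess_stack",
    "DEFAULT_PERIOD",
]

#: Nearest-integer number of 16-day steps per 365.25-day year.
DEFAULT_PERIOD = 23


@dataclass
class SpectralBands:
    """Co-registered red and near-infrared surface reflectance ([0, 1])."""

    rho_red: np.ndarray
    rho_nir: np.ndarray

    def __post_init__(self):
        self.rho_red = np.asarray(self.rho_red, dtype=float)
        self.rho_nir = np.asarray(self.rho_nir, dtype=float)
        if self.rho_red.shape != self.rho_nir.shape:
            raise ValueError("red and NIR band shapes differ")


@dataclass
class Decomposition:
    """Additive split of a series: input = trend + seasonal + remainder."""

    trend: np.ndarray
    seasonal: np.ndarray
    remainder: np.ndarray
    period: int

    @property
    def reconstruction(self) -> np.ndarray:
        return self.trend + self.seasonal + self.remainder


def compute_ndvi(bands: SpectralBands) -> tuple[np.ndarray, np.ndarray]:
    """NDVI from red/NIR reflectance.

    Returns
    -------
    ndvi : array, same shape as the bands; NaN where undefined
    missing : bool array, True where the denominator is zero
    """
    red, nir = bands.rho_red, bands.rho_nir
    if not (np.isfinite(red).all() and np.isfinite(nir).all()):
        raise ValueError("reflectances must be finite")
    denom = nir + red
    missing = denom == 0
    ndvi = np.full(red.shape, np.nan)
    np.divide(nir - red, denom, out=ndvi, where=~missing)
    return ndvi, missing


def build_time_grid(start_date, end_date, step_days: int = 16) -> pd.DatetimeIndex:
    """Inclusive arithmetic date grid from ``start_date`` every ``step_days``.

    The last element is the largest grid date <= ``end_date``; when the
    span is divisible by the step it equals ``end_date`` exactly.
    """
    start = pd.Timestamp(start_date)
    end = pd.Timestamp(end_date)
    if end < start:
        raise ValueError("end_date before start_date")
    if step_days < 1:
        raise ValueError("step_days must be >= 1")
    n = (end - start).days // step_days + 1
    return pd.DatetimeIndex([start + timedelta(days=step_days * i) for i in range(n)])


def infill_series(series: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Fill missing observations by linear interpolation in time.

    Observed values are returned untouched.  Interior gaps are linear
    between the two bracketing observations; leading/trailing gaps are
    constant-extended from the nearest observation, which keeps values
    inside the physical range.  All-missing input raises.
    """
    series = np.asarray(series, dtype=float)
    if mask is None:
        mask = np.isnan(series)
    else:
        mask = np.asarray(mask, dtype=bool)
    observed = ~mask & np.isfinite(series)
    if not observed.any():
        raise ValueError("series has no observed values")
    idx = np.arange(series.size)
    out = series.copy()
    # np.interp clamps outside the observed range = constant extension
    out[~observed] = np.interp(idx[~observed], idx[observed], series[observed])
    return out


def decompose_series(series: np.ndarray, period: int = DEFAULT_PERIOD) -> Decomposition:
    """LOESS-based seasonal-trend decomposition (STL) of a complete series.

    The seasonal sub-series (one per phase of the cycle) are smoothed
    across years with a periodic seasonal window; the trend window is
    the STL default (smallest odd integer above 1.5 * period / (1 -
    1.5/seasonal), effectively ~1.5 periods for a periodic seasonal).
    """
    series = np.asarray(series, dtype=float)
    if np.isnan(series).any():
        raise ValueError("series must be complete (infill first)")
    if series.size < 2 * period:
        raise ValueError("series shorter than two periods")
    res = STL(series, period=period, seasonal=period if period % 2 else period + 1).fit()
    seasonal = np.asarray(res.seasonal)
    trend = np.asarray(res.trend)
    # re-centre: the level belongs to the trend, the cycle to the seasonal
    offset = seasonal.mean()
    return Decomposition(
        trend=trend + offset,
        seasonal=seasonal - offset,
        remainder=np.asarray(res.resid),
        period=period,
    )


def filter_series(decomp: Decomposition) -> np.ndarray:
    """Recombine trend + seasonal, discarding the remainder."""
    return decomp.trend + decomp.seasonal


def preprocess_stack(stack: NDVIStack, period: int = DEFAULT_PERIOD) -> NDVIStack:
    """Infill, decompose, and filter every pixel of a stack.

    Returns a gap-free stack of trend+seasonal series clamped to the
    physical NDVI range [-1, 1]; geo-metadata and pixel order are
    preserved.  A pixel with no observations at all raises, naming it.
    """
    T, R, C = stack.shape
    out = np.empty_like(stack.values)
    for r in range(R):
        for c in range(C):
            series = stack.values[:, r, c]
            m = stack.mask[:, r, c]
            try:
                complete = infill_series(series, m)
            except ValueError as exc:
                raise ValueError(f"pixel (row={r}, col={c}): {exc}") from exc
            filtered = filter_series(decompose_series(complete, period))
            out[:, r, c] = np.clip(filtered, -1.0, 1.0)
    return NDVIStack(
        values=out,
        mask=np.zeros_like(stack.mask),
        dates=stack.dates,
        transform=stack.transform,
        crs=stack.crs,
    )
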