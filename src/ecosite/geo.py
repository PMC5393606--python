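"""Minimal affine georeferencing for north-up (or sheared) raster grids.

A :class:`GeoTransform` holds the six GDAL-style coefficients mapping
0-based (row, col) pixel indices to map coordinates.  World coordinates
refer to pixel *centres*; ``rowcol`` is the exact inverse for any
non-degenerate transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GeoTransform"]


@dataclass(frozen=True)
class GeoTransform:
    """GDAL-ordered affine coefficients (c, a, b, f, d, e).

    x = c + a * (col + 0.5) + b * (row + 0.5)
    y = f + d * (col + 0.5) + e * (row + 0.5)

    with (c, f) the map coordinates of the raster's upper-left corner.
    """

    c: float  # upper-left x
    a: float  # pixel width (x per col)
    b: float  # row rotation (x per row), usually 0
    f: float  # upper-left y
    d: float  # col rotation (y per col), usually 0
    e: float  # pixel height (y per row), usually negative

    @classmethod
    def north_up(cls, origin_x: float, origin_y: float, pixel_size: float) -> "GeoTransform":
        return cls(c=origin_x, a=pixel_size, b=0.0, f=origin_y, d=0.0, e=-pixel_size)

    def xy(self, row, col):
        """Map coordinates of pixel centre(s)."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.c + self.a * (col + 0.5) + self.b * (row + 0.5)
        y = self.f + self.d * (col + 0.5) + self.e * (row + 0.5)
        return x, y

    def rowcol(self, x, y):
        """0-based (row, col) of the pixel containing map point(s) (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ValueError("degenerate geotransform (zero determinant)")
        dx = x - self.c
        dy = y - self.f
        colf = (self.e * dx - self.b * dy) / det
        rowf = (-self.d * dx + self.a * dy) / det
        return np.floor(rowf).astype(int), np.floor(colf).astype(int)

    def to_dict(self) -> dict:
        return {"c": self.c, "a": self.a, "b": self.b, "f": self.f, "d": self.d, "e": self.e}

    @classmethod
    def from_dict(cls, d: dict) -> "GeoTransform":
        return cls(**{k: float(d[k]) for k in ("c", "a", "b", "f", "d", "e")})
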