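"""Minimal single-band raster container with Esri ASCII grid I/O.

Canopy-height models and reflectance maps are carried as a numpy array plus
an affine anchor (lower-left corner, square cells). The Esri ASCII grid
format is used on disk: it is plain text, self-describing, and readable by
every GIS stack.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Raster:
    """A single-band raster.

    ``values[row, col]`` with row 0 at the *top* (north), matching the usual
    image convention. ``xll, yll`` anchor the lower-left corner of the
    lower-left cell; ``resolution`` is the square cell size in metres.
    """

    values: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    resolution: float = 1.0
    nodata: float = -9999.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def x_coords(self) -> np.ndarray:
        """Pixel-center x coordinates, one per column."""
        ncol = self.values.shape[1]
        return self.xll + (np.arange(ncol) + 0.5) * self.resolution

    def y_coords(self) -> np.ndarray:
        """Pixel-center y coordinates, one per row (row 0 = northernmost)."""
        nrow = self.values.shape[0]
        return self.yll + (nrow - np.arange(nrow) - 0.5) * self.resolution

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of pixel-center (x, y), each shaped like ``values``."""
        xs, ys = np.meshgrid(self.x_coords(), self.y_coords())
        return xs, ys


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    v = np.asarray(raster.values, dtype=float)
    header = (
        f"ncols {v.shape[1]}\n"
        f"nrows {v.shape[0]}\n"
        f"xllcorner {raster.xll}\n"
        f"yllcorner {raster.yll}\n"
        f"cellsize {raster.resolution}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    body = np.where(np.isnan(v), raster.nodata, v)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> Raster:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    return Raster(
        values=values,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        resolution=header["cellsize"],
        nodata=nodata,
    )
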