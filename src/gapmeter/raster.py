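"""Minimal single-band raster container with ESRI ASCII grid I/O.

All rasters in the package live in one planar, projected coordinate system
(meters).  Row 0 is the *top* row, matching the ASCII-grid convention; the
grid origin (``xllcorner``/``yllcorner``) is the lower-left corner of the
extent.  Values are float64; NaN encodes missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band raster: ``data[row, col]`` with row 0 at the top."""

    data: np.ndarray
    cell_size: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates, each shaped like ``data``."""
        n_rows, n_cols = self.data.shape
        xs = self.x0 + (np.arange(n_cols) + 0.5) * self.cell_size
        ys = self.y0 + (n_rows - np.arange(n_rows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def like(self, data: np.ndarray) -> "Raster":
        """New raster sharing this raster's georeferencing."""
        if np.shape(data) != self.data.shape:
            raise ValueError("shape mismatch")
        return Raster(np.asarray(data, dtype=float), self.cell_size, self.x0, self.y0)


def write_ascii(raster: Raster, path: str | Path) -> None:
    data = np.where(np.isnan(raster.data), _NODATA, raster.data)
    n_rows, n_cols = raster.shape
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {raster.x0!r}\n"
        f"yllcorner {raster.y0!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {_NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.10g")


def read_ascii(path: str | Path) -> Raster:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            meta[key.lower()] = float(value)
        data = np.loadtxt(fh, ndmin=2)
    nodata = meta.get("nodata_value", _NODATA)
    data = np.where(data == nodata, np.nan, data)
    if data.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError(f"ASCII grid shape mismatch in {path}")
    return Raster(data, meta["cellsize"], meta["xllcorner"], meta["yllcorner"])
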