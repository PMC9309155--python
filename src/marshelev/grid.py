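"""Analysis grid and raster containers.

All pipeline layers live on a single shared :class:`AnalysisGrid`:
cell-center registered, origin at the upper-left corner, row-major storage
(row 0 is the northernmost row).  Rasters are plain float64 numpy arrays
with an explicit nodata sentinel; file exchange uses the ESRI ASCII grid
format, a plain-text raster format understood by standard GIS tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: default nodata sentinel for float rasters
NODATA = -3.4e38


@dataclass(frozen=True)
class AnalysisGrid:
    """A regular raster grid in a projected metric CRS.

    Parameters
    ----------
    origin_x, origin_y : float
        Coordinates of the *upper-left corner* of the grid, metres.
    n_rows, n_cols : int
        Grid shape; row 0 is the top (largest y).
    cell_size : float
        Square cell edge, metres (30 m for the analysis grid).
    crs : str
        Free-text token naming the coordinate system; all layers of a
        pipeline must share it.
    """

    origin_x: float
    origin_y: float
    n_rows: int
    n_cols: int
    cell_size: float = 30.0
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) arrays of shape (n_rows, n_cols) of cell centers."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col); points outside get indices out of range."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def same_as(self, other: "AnalysisGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
            and self.crs == other.crs
        )


@dataclass
class Raster:
    """A single-band raster on an :class:`AnalysisGrid`."""

    grid: AnalysisGrid
    values: np.ndarray
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        with np.errstate(invalid="ignore"):
            return (self.values != self.nodata) & ~np.isnan(self.values)

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=~self.mask)

    def filled(self, fill: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[~self.mask] = fill
        return out

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(self.grid, np.asarray(values, dtype=float), self.nodata)


def check_aligned(*rasters: Raster) -> AnalysisGrid:
    """Assert all rasters share one grid; return it."""
    g0 = rasters[0].grid
    for r in rasters[1:]:
        if not g0.same_as(r.grid):
            raise ValueError("rasters are not on the same analysis grid")
    return g0


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (text raster exchange format)

def write_ascii_grid(path: str | Path, raster: Raster, fmt: str = "%.6f") -> None:
    grid = raster.grid
    xll = grid.origin_x
    yll = grid.origin_y - grid.n_rows * grid.cell_size
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {float(xll)!r}\n"
        f"yllcorner {float(yll)!r}\n"
        f"cellsize {float(grid.cell_size)!r}\n"
        f"NODATA_value {float(raster.nodata)!r}\n"
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt=fmt)


def read_ascii_grid(path: str | Path, crs: str = "local-metric") -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    values = values.reshape(n_rows, n_cols)
    cell = header["cellsize"]
    grid = AnalysisGrid(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        crs=crs,
    )
    return Raster(grid, values, nodata=header.get("nodata_value", NODATA))
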