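"""Elevation tile preparation.

Raw elevation tiles (LiDAR-derived DEM analogs, metres NAVD88) are turned
into one bias-corrected raster on the 30 m analysis grid in four steps:
mask hydro-flattened water sentinels, resample each tile by area-weighted
mean, mosaic chronologically (newest survey wins where tiles overlap), and
subtract the vegetation bias offset.  A final step builds the area-of-
interest mask from the land-cover raster and the probabilistic
below-MHHWS layer.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .grid import NODATA, AnalysisGrid, Raster, check_aligned

logger = logging.getLogger(__name__)


@dataclass
class ElevationTile:
    """A dated elevation grid in its native resolution.

    The tile is georeferenced the same way as :class:`AnalysisGrid`
    (upper-left corner origin, row-major, north-up).
    """

    tile_id: str
    values: np.ndarray            # metres NAVD88
    origin_x: float
    origin_y: float
    resolution: float             # metres, native cell size
    date: _dt.date
    nodata: float = NODATA
    hydro_sentinel: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("tile values must be 2-D")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if isinstance(self.date, str):
            self.date = _dt.date.fromisoformat(self.date)

    @property
    def mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return (self.values != self.nodata) & ~np.isnan(self.values)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        n_rows, n_cols = self.values.shape
        x = self.origin_x + (np.arange(n_cols) + 0.5) * self.resolution
        y = self.origin_y - (np.arange(n_rows) + 0.5) * self.resolution
        return np.meshgrid(x, y)


def parse_tile_date(name: str, metadata_date: str | None = None) -> _dt.date:
    """Tile date from metadata if present, else first 8-digit token in the name."""
    if metadata_date:
        return _dt.date.fromisoformat(metadata_date)
    digits = ""
    for ch in name:
        if ch.isdigit():
            digits += ch
            if len(digits) == 8:
                return _dt.date(int(digits[:4]), int(digits[4:6]), int(digits[6:8]))
        else:
            digits = ""
    raise ValueError(f"no parseable date in tile name {name!r}")


def mask_hydroflat(tile: ElevationTile) -> ElevationTile:
    """Replace hydro-flattened water sentinel cells with nodata.

    Hydro-flattening assigns mapped surface water an arbitrary low value;
    those cells must never enter resampling means.
    """
    if tile.hydro_sentinel is None:
        raise ValueError(f"tile {tile.tile_id}: hydro sentinel not documented")
    if tile.hydro_sentinel > -10.0:
        logger.warning(
            "tile %s: hydro sentinel %.3f m is within plausible land elevations",
            tile.tile_id,
            tile.hydro_sentinel,
        )
    values = tile.values.copy()
    values[values == tile.hydro_sentinel] = tile.nodata
    return replace(tile, values=values, hydro_sentinel=None)


def resample_to_grid(tile: ElevationTile, grid: AnalysisGrid) -> ElevationTile:
    """Area-weighted mean resampling of a native tile onto the analysis grid.

    Every non-nodata native cell whose center falls in an analysis cell
    contributes equally to that cell's mean; a cell is nodata only when all
    contributors are nodata (an unbinned continuous product, not minimum
    binning).
    """
    xs, ys = tile.cell_centers()
    row, col = grid.index_of(xs, ys)
    inside = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
    valid = inside & tile.mask
    if not inside.any():
        raise ValueError(f"tile {tile.tile_id} does not overlap the analysis grid")

    sums = np.zeros(grid.shape)
    counts = np.zeros(grid.shape)
    flat = row[valid] * grid.n_cols + col[valid]
    np.add.at(sums.ravel(), flat, tile.values[valid])
    np.add.at(counts.ravel(), flat, 1.0)

    out = np.full(grid.shape, tile.nodata)
    hit = counts > 0
    out[hit] = sums[hit] / counts[hit]
    return ElevationTile(
        tile_id=tile.tile_id,
        values=out,
        origin_x=grid.origin_x,
        origin_y=grid.origin_y,
        resolution=grid.cell_size,
        date=tile.date,
        nodata=tile.nodata,
        hydro_sentinel=None,
    )


def mosaic_chronological(
    tiles: list[ElevationTile], grid: AnalysisGrid
) -> ElevationTile:
    """Mosaic same-grid tiles so the most recent survey wins on overlap.

    Nodata in a newer tile falls through to the next-newest valid value.
    Ties on date break lexicographically on tile id (deterministic builds).
    """
    if not tiles:
        raise ValueError("no tiles to mosaic")
    for t in tiles:
        if t.values.shape != grid.shape or t.resolution != grid.cell_size:
            raise ValueError(f"tile {t.tile_id} is not on the analysis grid")
    order = sorted(tiles, key=lambda t: (t.date, t.tile_id), reverse=True)
    dates = [t.date for t in tiles]
    if len(set(dates)) < len(dates):
        logger.info("duplicate tile dates; breaking ties on tile id")

    out = np.full(grid.shape, NODATA)
    filled = np.zeros(grid.shape, dtype=bool)
    for t in order:
        take = t.mask & ~filled
        out[take] = t.values[take]
        filled |= take
    return ElevationTile(
        tile_id="mosaic",
        values=out,
        origin_x=grid.origin_x,
        origin_y=grid.origin_y,
        resolution=grid.cell_size,
        date=max(dates),
        nodata=NODATA,
    )


def bias_correct(tile: ElevationTile, offset: float) -> ElevationTile:
    """Subtract the vegetation bias offset from every valid cell.

    LiDAR overestimates ground elevation under marsh vegetation; the
    national-scale correction is a single weighted site-level average
    offset (default 0.173 m in the pipeline configuration).
    """
    if not np.isfinite(offset):
        raise ValueError("offset must be finite")
    values = tile.values.copy()
    m = tile.mask
    values[m] = values[m] - offset
    return replace(tile, values=values)


def tile_to_raster(tile: ElevationTile, grid: AnalysisGrid) -> Raster:
    if tile.values.shape != grid.shape:
        raise ValueError("tile is not on the analysis grid")
    return Raster(grid, tile.values, nodata=tile.nodata)


def prepare_dem(
    tiles: list[ElevationTile],
    grid: AnalysisGrid,
    offset: float = 0.173,
) -> Raster:
    """Full preparation chain: mask -> resample -> mosaic -> bias-correct."""
    staged = []
    for t in tiles:
        if t.hydro_sentinel is not None:
            t = mask_hydroflat(t)
        staged.append(resample_to_grid(t, grid))
    mosaic = mosaic_chronological(staged, grid)
    return tile_to_raster(bias_correct(mosaic, offset), grid)


# ---------------------------------------------------------------------------
# Area of interest

#: provenance codes written to the AOI provenance band
PROVENANCE = {
    "excluded": 0,
    "estuarine": 1,
    "palustrine-included": 2,
    "other-included": 3,
    "nwi-included": 4,
}


@dataclass(frozen=True)
class ClassCodes:
    """Integer codes of the land-cover legend (C-CAP analog).

    Codes are configuration, not constants: synthetic and real legends
    differ.
    """

    open_water: int = 1
    estuarine_emergent: int = 2
    palustrine: int = 3
    developed: int = 4
    upland: int = 5

    @property
    def conditional(self) -> tuple[int, ...]:
        """Classes included only where P(below MHHWS) exceeds the cutoff."""
        return (self.palustrine, self.developed, self.upland)


@dataclass
class AoiMask:
    """Boolean area-of-interest mask plus a per-pixel provenance band."""

    grid: AnalysisGrid
    include: np.ndarray           # bool
    provenance: np.ndarray        # uint8, see PROVENANCE

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        self.provenance = np.asarray(self.provenance, dtype=np.uint8)


def build_aoi(
    landcover: Raster,
    p_below_mhhws: Raster,
    codes: ClassCodes = ClassCodes(),
    p_cutoff: float = 0.01,
    nwi_mask: np.ndarray | None = None,
) -> AoiMask:
    """Area-of-interest rule.

    Estuarine emergent wetland is always in; palustrine / developed /
    upland classes are in only where the probability of lying below MHHWS
    exceeds ``p_cutoff`` (1% by default); open water is never in.  An
    optional tidal-wetland-inventory mask is unioned in last.
    """
    grid = check_aligned(landcover, p_below_mhhws)
    lc = landcover.values.astype(int)
    p = p_below_mhhws.values
    valid_p = p_below_mhhws.mask
    if ((p[valid_p] < 0) | (p[valid_p] > 1)).any():
        raise ValueError("probability layer has values outside [0, 1]")

    include = np.zeros(grid.shape, dtype=bool)
    prov = np.zeros(grid.shape, dtype=np.uint8)

    est = lc == codes.estuarine_emergent
    include[est] = True
    prov[est] = PROVENANCE["estuarine"]

    cond = np.isin(lc, codes.conditional) & valid_p & (p > p_cutoff)
    include[cond] = True
    prov[cond & (lc == codes.palustrine)] = PROVENANCE["palustrine-included"]
    prov[cond & (lc != codes.palustrine)] = PROVENANCE["other-included"]

    if nwi_mask is not None:
        nwi_new = np.asarray(nwi_mask, dtype=bool) & ~include
        include |= nwi_new
        prov[nwi_new] = PROVENANCE["nwi-included"]

    water = lc == codes.open_water
    include[water] = False
    prov[water] = PROVENANCE["excluded"]

    return AoiMask(grid, include, prov)
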