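"""Self-contained synthetic coastal world.

Every downstream stage of the pipeline is exercised against a generated
scene with the statistical structure the analysis assumes: a smooth true
marsh surface whose elevation relative to the tidal frame spans subtidal
to upland; observed elevation tiles carrying a per-tile (site-level)
vegetation bias plus per-pixel random error, with open water
hydro-flattened to a sentinel; a tide-gauge network whose MSL and MHW
errors are drawn jointly with a configurable correlation; a tidal
amplitude gradient that increases linearly from south to north; a
land-cover legend, latitudinal watershed polygons, and per-gauge water
level series.  Truth grids (true Z* and below-MHW labels) align exactly
with the analysis grid.

One master seed drives everything; independent child streams are spawned
deterministically per component so identical configurations reproduce
identical scenes bit for bit.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box, mapping

from .datum_fields import GaugeRecord, gauges_to_frame
from .dem_prep import ClassCodes, ElevationTile
from .grid import AnalysisGrid, Raster, write_ascii_grid

#: tidal constituent periods, hours (principal lunar semidiurnal, lunisolar diurnal)
M2_PERIOD_H = 12.4206012
K1_PERIOD_H = 23.9344696


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of a synthetic coastal scene.

    Defaults carry the error-model constants of the national analysis:
    vegetation bias 0.173 m with site-level SD 0.110 m, per-pixel random
    error 0.205 m, and MSL-MHW error correlation 0.873.
    """

    n_rows: int = 120
    n_cols: int = 160
    cell_size: float = 30.0
    grid_origin: tuple[float, float] = (0.0, 0.0)  # upper-left corner (x, y=top)
    n_gauges: int = 64
    n_tiles: int = 6
    tile_resolution: float = 10.0
    amplitude_range: tuple[float, float] = (0.6, 2.4)
    veg_bias_mean: float = 0.173
    veg_bias_site_sd: float = 0.110
    random_error_sd: float = 0.205
    datum_error_scale: float = 0.02
    rho_msl_mhw: float = 0.873
    water_fraction: float = 0.15
    n_watersheds: int = 24
    hydro_sentinel: float = -9999.0
    rslr_range_mm_yr: tuple[float, float] = (9.0, 2.0)  # south -> north
    noise_correlation_range: float | None = None  # metres; None = iid pixel noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gauges < 3:
            raise ValueError("need at least 3 gauges")
        if self.n_watersheds < 2:
            raise ValueError("need at least 2 watersheds")
        if self.n_tiles < 2:
            raise ValueError("need at least 2 tiles (with overlap)")
        if self.cell_size <= 0 or self.tile_resolution <= 0:
            raise ValueError("cell sizes must be positive")
        if min(self.amplitude_range) <= 0:
            raise ValueError("tidal amplitude must be positive everywhere")
        if not abs(self.rho_msl_mhw) <= 1:
            raise ValueError("|rho_msl_mhw| must be <= 1")
        if not 0 <= self.water_fraction < 1:
            raise ValueError("water_fraction must be in [0, 1)")
        if self.veg_bias_site_sd < 0 or self.random_error_sd < 0:
            raise ValueError("error SDs must be nonnegative")

    @property
    def grid(self) -> AnalysisGrid:
        return AnalysisGrid(
            origin_x=self.grid_origin[0],
            origin_y=self.grid_origin[1]
            if self.grid_origin[1] != 0.0
            else self.n_rows * self.cell_size,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            cell_size=self.cell_size,
        )


@dataclass
class WaterLevelSeries:
    """A water-level time series with its generating constituents."""

    gauge_id: str
    times: pd.DatetimeIndex
    level_m: np.ndarray
    msl: float
    constituents: list[tuple[str, float, float, float]]  # (name, amp, period_h, phase)
    trend_mm_yr: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.times, "level_m": self.level_m})

    def astronomic_level(self, t_hours: np.ndarray) -> np.ndarray:
        """Noise-free constituent reconstruction at hours since series start."""
        t_hours = np.asarray(t_hours, dtype=float)
        out = np.full(t_hours.shape, self.msl)
        for _, amp, period, phase in self.constituents:
            out = out + amp * np.cos(2 * np.pi * t_hours / period + phase)
        return out


@dataclass
class SyntheticScene:
    """All layers of one generated coastal world."""

    config: SceneConfig
    grid: AnalysisGrid
    true_surface: Raster                  # m NAVD88
    msl_true: Raster
    mhw_true: Raster
    mhhw_true: Raster
    mhhws_true: Raster
    amplitude_true: Raster                # MHW - MSL, m
    water_mask: np.ndarray                # bool, open water cells
    landcover: Raster                     # class codes
    class_codes: ClassCodes
    observed_tiles: list[ElevationTile]
    gauges: list[GaugeRecord]
    gauge_rslr_mm_yr: dict[str, float]
    watersheds: list[tuple[str, object]]  # (id, shapely polygon)
    water_levels: dict[str, WaterLevelSeries]
    monthly_levels: dict[str, pd.DataFrame]
    true_zstar: Raster
    true_below_mhw: np.ndarray            # bool labels on land cells


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma_cells: float, sd: float) -> np.ndarray:
    """Mean-zero smooth Gaussian random field with pointwise SD ``sd``."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma_cells, mode="reflect")
    s = sm.std()
    return sm * (sd / s) if s > 0 else sm


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate one synthetic coastal scene from its configuration."""
    grid = config.grid
    ss = np.random.SeedSequence(config.seed)
    (seed_surface, seed_gauges, seed_tiles,
     seed_tides, seed_monthly) = ss.spawn(5)

    xs, ys = grid.cell_centers()
    xmin, ymin, xmax, ymax = grid.extent
    u = (xs - xmin) / (xmax - xmin)       # 0 west -> 1 east
    t = (ys - ymin) / (ymax - ymin)       # 0 south -> 1 north

    # --- true tidal frame: amplitude grows linearly south -> north
    amin, amax = config.amplitude_range
    amplitude = amin + (amax - amin) * t
    msl = 0.10 * t + 0.03 * np.sin(2 * np.pi * u)
    mhw = msl + amplitude
    dhq = 0.10 * amplitude                # diurnal inequality analog
    mhhw = mhw + dhq
    mhhws = mhhw + 0.08 * amplitude

    # --- true ground surface: relative elevation spans subtidal to upland
    rng_surface = np.random.default_rng(seed_surface)
    zstar_true = (
        -1.0 + 4.0 * u
        + 0.6 * np.sin(3 * np.pi * u + 1.3) * np.cos(2 * np.pi * t)
        + _smooth_field(rng_surface, grid.shape, sigma_cells=6.0, sd=0.35)
    )
    true_surface = msl + zstar_true * amplitude

    # --- open water: lowest relative elevations, matching water_fraction
    if config.water_fraction > 0:
        thresh = np.quantile(zstar_true, config.water_fraction)
        water = zstar_true <= thresh
    else:
        water = np.zeros(grid.shape, dtype=bool)

    # --- land cover legend
    codes = ClassCodes()
    lc = np.full(grid.shape, codes.upland, dtype=float)
    lc[zstar_true <= 1.5] = codes.estuarine_emergent
    lc[(zstar_true > 1.5) & (zstar_true <= 2.2)] = codes.palustrine
    dev = (u > 0.85) & (zstar_true > 2.2)
    lc[dev] = codes.developed
    lc[water] = codes.open_water

    # --- gauges on a jittered quasi-regular layout
    rng_g = np.random.default_rng(seed_gauges)
    n_g = config.n_gauges
    gx = xmin + (xmax - xmin) * ((np.arange(n_g) + 0.5) / n_g)
    gy = ymin + (ymax - ymin) * rng_g.permutation((np.arange(n_g) + 0.5) / n_g)
    gx = gx + rng_g.uniform(-0.02, 0.02, n_g) * (xmax - xmin)
    gy = gy + rng_g.uniform(-0.02, 0.02, n_g) * (ymax - ymin)
    gy = np.clip(gy, ymin + 1, ymax - 1)
    gx = np.clip(gx, xmin + 1, xmax - 1)

    cov = (config.datum_error_scale**2) * np.array(
        [[1.0, config.rho_msl_mhw], [config.rho_msl_mhw, 1.0]]
    )
    err_msl_mhw = rng_g.multivariate_normal([0.0, 0.0], cov, size=n_g,
                                            method="cholesky")
    err_mhhw = err_msl_mhw[:, 1] + 0.5 * config.datum_error_scale * rng_g.standard_normal(n_g)
    err_mhhws = err_mhhw + 0.5 * config.datum_error_scale * rng_g.standard_normal(n_g)
    se_draw = config.datum_error_scale * rng_g.uniform(0.8, 1.2, size=(n_g, 4))

    row, col = grid.index_of(gx, gy)
    t_g = (gy - ymin) / (ymax - ymin)
    rs, rn = config.rslr_range_mm_yr
    rslr_true = rs + (rn - rs) * t_g

    gauges: list[GaugeRecord] = []
    gauge_rslr: dict[str, float] = {}
    for i in range(n_g):
        r, c = int(row[i]), int(col[i])
        gid = f"g{i:02d}"
        gauges.append(
            GaugeRecord(
                gauge_id=gid, x=float(gx[i]), y=float(gy[i]),
                msl=float(msl[r, c] + err_msl_mhw[i, 0]),
                mhw=float(mhw[r, c] + err_msl_mhw[i, 1]),
                mhhw=float(max(mhhw[r, c] + err_mhhw[i],
                               mhw[r, c] + err_msl_mhw[i, 1])),
                mhhws=float(mhhws[r, c] + err_mhhws[i]),
                se_msl=float(se_draw[i, 0]), se_mhw=float(se_draw[i, 1]),
                se_mhhw=float(se_draw[i, 2]), se_mhhws=float(se_draw[i, 3]),
                epoch="1983-2001",
            )
        )
        gauge_rslr[gid] = float(rslr_true[i])

    # --- observed tiles: native-resolution bands with overlap, dated
    tiles = _generate_tiles(config, grid, true_surface, water, seed_tiles)

    # --- watershed polygons: latitudinal bands
    watersheds = []
    edges = np.linspace(ymin, ymax, config.n_watersheds + 1)
    for i in range(config.n_watersheds):
        watersheds.append(
            (f"ws{i:02d}", box(xmin, edges[i], xmax, edges[i + 1]))
        )

    # --- water levels: one year of 6-min data + monthly means for RSLR
    water_levels: dict[str, WaterLevelSeries] = {}
    monthly: dict[str, pd.DataFrame] = {}
    tide_children = seed_tides.spawn(n_g)
    monthly_children = seed_monthly.spawn(n_g)
    for i, g in enumerate(gauges):
        water_levels[g.gauge_id] = generate_tide_series(
            g, years=1.0, step_minutes=6,
            seed=int(tide_children[i].generate_state(1)[0] % 2**31),
        )
        monthly[g.gauge_id] = generate_monthly_levels(
            g, gauge_rslr[g.gauge_id],
            seed=int(monthly_children[i].generate_state(1)[0] % 2**31),
        )

    true_zstar = (true_surface - msl) / amplitude
    return SyntheticScene(
        config=config,
        grid=grid,
        true_surface=Raster(grid, true_surface),
        msl_true=Raster(grid, msl),
        mhw_true=Raster(grid, mhw),
        mhhw_true=Raster(grid, mhhw),
        mhhws_true=Raster(grid, mhhws),
        amplitude_true=Raster(grid, amplitude),
        water_mask=water,
        landcover=Raster(grid, lc, nodata=-1.0),
        class_codes=codes,
        observed_tiles=tiles,
        gauges=gauges,
        gauge_rslr_mm_yr=gauge_rslr,
        watersheds=watersheds,
        water_levels=water_levels,
        monthly_levels=monthly,
        true_zstar=Raster(grid, true_zstar),
        true_below_mhw=(true_zstar < 1.0) & ~water,
    )


def _generate_tiles(
    config: SceneConfig,
    grid: AnalysisGrid,
    true_surface: np.ndarray,
    water: np.ndarray,
    seed: np.random.SeedSequence,
) -> list[ElevationTile]:
    """Observed tiles = true + per-tile site bias + per-pixel random error.

    Tiles are vertical bands (full grid height) with a two-cell overlap
    between neighbours and strictly increasing survey dates.
    """
    factor = int(round(grid.cell_size / config.tile_resolution))
    if factor < 1:
        raise ValueError("tile_resolution must not exceed cell_size")
    n_tiles = config.n_tiles
    children = seed.spawn(n_tiles)

    # column spans with overlap
    bounds = np.linspace(0, grid.n_cols, n_tiles + 1).astype(int)
    tiles: list[ElevationTile] = []
    for i in range(n_tiles):
        c0 = max(bounds[i] - 2, 0) if i > 0 else 0
        c1 = min(bounds[i + 1] + 2, grid.n_cols) if i < n_tiles - 1 else grid.n_cols
        rng = np.random.default_rng(children[i])
        block_true = np.kron(true_surface[:, c0:c1], np.ones((factor, factor)))
        block_water = np.kron(water[:, c0:c1],
                              np.ones((factor, factor), dtype=bool))
        bias = rng.normal(config.veg_bias_mean, config.veg_bias_site_sd)
        if config.noise_correlation_range:
            sigma_cells = config.noise_correlation_range / config.tile_resolution
            noise = _smooth_field(rng, block_true.shape, sigma_cells,
                                  config.random_error_sd)
        else:
            noise = rng.normal(0.0, config.random_error_sd, block_true.shape)
        observed = block_true + bias + noise
        observed[block_water] = config.hydro_sentinel
        tiles.append(
            ElevationTile(
                tile_id=f"tile{i:02d}_{2010 + i}0601",
                values=observed,
                origin_x=grid.origin_x + c0 * grid.cell_size,
                origin_y=grid.origin_y,
                resolution=config.tile_resolution,
                date=_dt.date(2010 + i, 6, 1),
                hydro_sentinel=config.hydro_sentinel,
            )
        )
    return tiles


def generate_tide_series(
    gauge: GaugeRecord,
    years: float,
    step_minutes: int,
    seed: int,
    amplitudes: tuple[float, float] | None = None,
    trend_mm_yr: float = 0.0,
    noise_sd: float = 0.0,
    phases: tuple[float, float] = (0.0, 1.1),
    start: str = "2015-01-01",
) -> WaterLevelSeries:
    """Mixed semidiurnal tide at a gauge: M2 + K1 constituent analogs.

    The diurnal constituent creates a nonzero diurnal high-tide
    inequality (MHHW > MHW).  Constituent amplitudes default to
    (0.85, 0.35) x the gauge's tidal amplitude.  An optional linear trend
    (mm/yr) and Gaussian noise can be added; the series mean stays at the
    gauge MSL up to partial-cycle and noise effects.
    """
    if years <= 0:
        raise ValueError("years must be positive")
    if (24 * 60) % step_minutes != 0:
        raise ValueError("step_minutes must divide a day")
    if amplitudes is not None and len(amplitudes) == 0:
        raise ValueError("at least one tidal constituent is required")
    a_m2, a_k1 = amplitudes if amplitudes is not None else (
        0.85 * gauge.amplitude, 0.35 * gauge.amplitude)

    n = int(round(years * 365.25 * 24 * 60 / step_minutes))
    times = pd.date_range(start, periods=n, freq=f"{step_minutes}min")
    t_hours = np.arange(n) * (step_minutes / 60.0)
    constituents = [
        ("M2", a_m2, M2_PERIOD_H, phases[0]),
        ("K1", a_k1, K1_PERIOD_H, phases[1]),
    ]
    level = np.full(n, gauge.msl)
    for _, amp, period, phase in constituents:
        level = level + amp * np.cos(2 * np.pi * t_hours / period + phase)
    if trend_mm_yr:
        level = level + (trend_mm_yr / 1000.0) * (t_hours / (24 * 365.25))
    if noise_sd:
        rng = np.random.default_rng(seed)
        level = level + rng.normal(0.0, noise_sd, n)
    return WaterLevelSeries(
        gauge_id=gauge.gauge_id,
        times=times,
        level_m=level,
        msl=gauge.msl,
        constituents=constituents,
        trend_mm_yr=trend_mm_yr,
    )


def generate_monthly_levels(
    gauge: GaugeRecord,
    trend_mm_yr: float,
    seed: int,
    start_year: int = 1983,
    end_year: int = 2001,
    noise_sd_mm: float = 25.0,
    completeness: float = 1.0,
) -> pd.DataFrame:
    """Monthly mean sea level (mm, station datum analog) with a linear trend.

    Emulates the long-term gauge record used for relative sea-level rise;
    ``completeness`` < 1 drops a random subset of months.
    """
    months = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-01", freq="MS")
    frac_year = months.year + (months.month - 0.5) / 12.0
    rng = np.random.default_rng(seed)
    level = (
        gauge.msl * 1000.0
        + trend_mm_yr * (frac_year - frac_year[0])
        + rng.normal(0.0, noise_sd_mm, len(months))
    )
    frame = pd.DataFrame({"timestamp": months, "level_mm": level})
    if completeness < 1.0:
        keep = rng.random(len(frame)) < completeness
        frame = frame[keep].reset_index(drop=True)
    return frame


# ---------------------------------------------------------------------------
# Scene writer

def write_scene(scene: SyntheticScene, out_dir: str | Path) -> None:
    """Write a scene to disk as text layers (ASCII grids, CSV, GeoJSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tiles_dir = out / "tiles"
    tiles_dir.mkdir(exist_ok=True)
    for t in scene.observed_tiles:
        tile_raster = Raster(
            AnalysisGrid(t.origin_x, t.origin_y, *t.values.shape,
                         cell_size=t.resolution),
            t.values, nodata=t.nodata,
        )
        write_ascii_grid(tiles_dir / f"{t.tile_id}.asc", tile_raster, fmt="%.4f")

    gauges_to_frame(scene.gauges).to_csv(out / "gauges.csv", index=False)
    pd.DataFrame(
        {"id": list(scene.gauge_rslr_mm_yr),
         "rslr_mm_yr": list(scene.gauge_rslr_mm_yr.values())}
    ).to_csv(out / "gauge_rslr_true.csv", index=False)

    write_ascii_grid(out / "landcover.asc", scene.landcover, fmt="%d")
    write_ascii_grid(out / "true_surface.asc", scene.true_surface, fmt="%.4f")
    write_ascii_grid(out / "true_zstar.asc", scene.true_zstar, fmt="%.4f")

    features = [
        {
            "type": "Feature",
            "properties": {"huc_id": wid},
            "geometry": mapping(geom),
        }
        for wid, geom in scene.watersheds
    ]
    (out / "watersheds.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )

    wl_dir = out / "water_levels"
    wl_dir.mkdir(exist_ok=True)
    for gid, series in scene.water_levels.items():
        series.to_frame().to_csv(wl_dir / f"{gid}.csv", index=False)
    ml_dir = out / "monthly_levels"
    ml_dir.mkdir(exist_ok=True)
    for gid, frame in scene.monthly_levels.items():
        frame.to_csv(ml_dir / f"{gid}.csv", index=False)
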