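"""End-to-end pipeline: scene -> DEM -> datums -> Z* -> classes -> trends.

Each stage writes its artifacts plus a JSON manifest (declared inputs,
parameter hash, outputs) into the run directory; manifests contain no
timestamps, so a rerun with the same configuration and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dem_prep, flood_class, trend_models, watershed_stats
from .datum_fields import (
    DatumField,
    compose_transformation_error,
    fit_variogram,
    gauges_from_frame,
    interpolate_datum,
    krige_points,
)
from .dem_prep import ElevationTile, parse_tile_date, prepare_dem
from .flood_class import PIXEL_AREA_HA, binomial_area, classify_binary, error_normalize, prob_below
from .grid import NODATA, AnalysisGrid, Raster, read_ascii_grid, write_ascii_grid
from .synthetic_scene import SceneConfig, SyntheticScene, generate_scene, write_scene
from .zstar import ErrorBudget, compute_zstar_raster

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one pipeline run, serializable to YAML.

    The constants carry the national-analysis defaults: vegetation bias
    0.173 m, random error 0.205 m, bias SE 0.110 m, datum-chain
    correlation rho = 0.716, MSL-MHW correlation rho2 = 0.873, low-marsh
    threshold Z* = 1, AOI inclusion probability 0.01.
    """

    scene: SceneConfig = field(default_factory=SceneConfig)
    offset: float = 0.173
    sigma_random: float = 0.205
    sigma_bias: float = 0.110
    rho: float = 0.716
    rho2: float = 0.873
    threshold: float = 1.0
    aoi_cutoff: float = 0.01
    idw_power: float = 2.0
    as_printed_partials: bool = False
    include_outliers: tuple[str, ...] = ()
    min_model_n: int = 10

    @property
    def budget(self) -> ErrorBudget:
        return ErrorBudget(self.sigma_random, self.sigma_bias, self.rho2)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["include_outliers"] = list(self.include_outliers)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        scene_kwargs = data.pop("scene", {})
        for key in ("grid_origin", "amplitude_range", "rslr_range_mm_yr"):
            if key in scene_kwargs and scene_kwargs[key] is not None:
                scene_kwargs[key] = tuple(scene_kwargs[key])
        data["include_outliers"] = tuple(data.get("include_outliers", ()))
        return cls(scene=SceneConfig(**scene_kwargs), **data)


def _param_hash(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(run_dir: Path, stage: str, inputs: list[str],
                    outputs: list[str], params: dict) -> None:
    manifest = {
        "stage": stage,
        "inputs": sorted(inputs),
        "outputs": sorted(outputs),
        "param_hash": _param_hash(params),
    }
    (run_dir / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )


def load_tiles(tiles_dir: str | Path, hydro_sentinel: float) -> list[ElevationTile]:
    """Read elevation tiles from ASCII grids, dating them from file names."""
    tiles = []
    for path in sorted(Path(tiles_dir).glob("*.asc")):
        raster = read_ascii_grid(path)
        tiles.append(
            ElevationTile(
                tile_id=path.stem,
                values=raster.values,
                origin_x=raster.grid.origin_x,
                origin_y=raster.grid.origin_y,
                resolution=raster.grid.cell_size,
                date=parse_tile_date(path.stem),
                nodata=raster.nodata,
                hydro_sentinel=hydro_sentinel,
            )
        )
    if not tiles:
        raise FileNotFoundError(f"no .asc tiles under {tiles_dir}")
    return tiles


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage on a generated scene; returns the run directory."""
    run = Path(out_dir)
    run.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run / "config.yml")

    # --- simulate
    scene = generate_scene(config.scene)
    write_scene(scene, run / "scene")
    _write_manifest(run, "simulate", [], ["scene/"],
                    {"scene": dataclasses.asdict(config.scene)})

    grid = scene.grid
    budget = config.budget

    # --- prep-dem
    dem = prepare_dem(scene.observed_tiles, grid, offset=config.offset)
    write_ascii_grid(run / "dem.asc", dem, fmt="%.4f")
    _write_manifest(run, "prep_dem", ["scene/tiles/"], ["dem.asc"],
                    {"offset": config.offset})

    # --- interp-datums
    datums: dict[str, DatumField] = {}
    datum_dir = run / "datums"
    datum_dir.mkdir(exist_ok=True)
    for which in ("msl", "mhw", "mhhw", "mhhws"):
        fieldd = interpolate_datum(scene.gauges, which, grid, power=config.idw_power)
        datums[which] = fieldd
        write_ascii_grid(datum_dir / f"{which}.asc", fieldd.value, fmt="%.4f")
        write_ascii_grid(datum_dir / f"{which}_se.asc", fieldd.se_total, fmt="%.5f")
    # the MHHWS surface sits on a chained datum transformation; its error
    # combines the MHHW and MHHWS-offset errors with correlation rho
    se_mhhws_chain = compose_transformation_error(
        datums["mhhw"].se_total.values, datums["mhhws"].se_total.values, config.rho
    )
    write_ascii_grid(datum_dir / "mhhws_se_chain.asc",
                     Raster(grid, se_mhhws_chain), fmt="%.5f")
    _write_manifest(run, "interp_datums", ["scene/gauges.csv"],
                    ["datums/"], {"power": config.idw_power, "rho": config.rho})

    # --- probabilistic below-MHHWS layer and AOI
    sigma_below = np.sqrt(budget.sigma_z**2 + se_mhhws_chain**2)
    zprime_mhhws = Raster(
        grid,
        np.where(dem.mask,
                 (datums["mhhws"].value.values - dem.values) / sigma_below,
                 NODATA),
    )
    p_mhhws = prob_below(zprime_mhhws, threshold_used=0.0)
    write_ascii_grid(run / "p_below_mhhws.asc", p_mhhws.p, fmt="%.2f")
    aoi = dem_prep.build_aoi(scene.landcover, p_mhhws.p,
                             codes=scene.class_codes, p_cutoff=config.aoi_cutoff)
    write_ascii_grid(run / "aoi.asc", Raster(grid, aoi.include.astype(float)),
                     fmt="%d")
    _write_manifest(run, "aoi", ["dem.asc", "datums/", "scene/landcover.asc"],
                    ["p_below_mhhws.asc", "aoi.asc"],
                    {"cutoff": config.aoi_cutoff})

    # --- zstar
    zsr = compute_zstar_raster(
        dem, datums["msl"].value, datums["mhw"].value,
        datums["msl"].se_total, datums["mhw"].se_total,
        budget=budget, as_printed=config.as_printed_partials,
    )
    write_ascii_grid(run / "zstar.asc", zsr.zstar, fmt="%.4f")
    write_ascii_grid(run / "zstar_sigma.asc", zsr.sigma, fmt="%.4f")
    write_ascii_grid(run / "amplitude.asc", zsr.amplitude, fmt="%.4f")
    _write_manifest(run, "zstar", ["dem.asc", "datums/"],
                    ["zstar.asc", "zstar_sigma.asc"],
                    {"budget": dataclasses.asdict(budget),
                     "as_printed": config.as_printed_partials})

    # --- classify
    zprime = error_normalize(zsr.zstar, zsr.sigma, x=config.threshold)
    p_low = prob_below(zprime, threshold_used=config.threshold)
    p_high = p_low.complement()
    write_ascii_grid(run / "p_low.asc", p_low.p, fmt="%.2f")
    write_ascii_grid(run / "p_high.asc", p_high.p, fmt="%.2f")
    write_ascii_grid(run / "class_low.asc", classify_binary(p_low), fmt="%d")

    estuarine = (
        scene.landcover.values == scene.class_codes.estuarine_emergent
    ) & aoi.include
    pixel_area = PIXEL_AREA_HA * (grid.cell_size / 30.0) ** 2
    rows = []
    for wid, geom in scene.watersheds:
        sel = watershed_stats.pixels_in_polygon(p_low.p, geom, estuarine)
        if not sel.any():
            continue
        for cls, pr in (("low", p_low), ("high", p_high)):
            est = binomial_area(pr, pixel_area=pixel_area, mask=sel)
            rows.append({"zone": wid, "class": cls,
                         "mean_ha": est.mean_area, "sd_ha": est.sd_area})
    for cls, pr in (("low", p_low), ("high", p_high)):
        est = binomial_area(pr, pixel_area=pixel_area, mask=estuarine)
        rows.append({"zone": "ALL", "class": cls,
                     "mean_ha": est.mean_area, "sd_ha": est.sd_area})
    areas = pd.DataFrame(rows)
    areas.to_csv(run / "areas.csv", index=False, float_format="%.4f")
    _write_manifest(run, "classify", ["zstar.asc", "zstar_sigma.asc", "aoi.asc"],
                    ["p_low.asc", "p_high.asc", "class_low.asc", "areas.csv"],
                    {"threshold": config.threshold})

    # --- RSLR surface from monthly gauge records
    rslr_by_gauge = {}
    for gid, monthly in scene.monthly_levels.items():
        try:
            rslr_by_gauge[gid] = trend_models.estimate_rslr(monthly)
        except trend_models.IncompleteRecordError as exc:
            logger.info("gauge %s excluded from RSLR: %s", gid, exc)
    coords = np.array(
        [[g.x, g.y] for g in scene.gauges if g.gauge_id in rslr_by_gauge]
    )
    vals = np.array([rslr_by_gauge[g.gauge_id] for g in scene.gauges
                     if g.gauge_id in rslr_by_gauge])
    xs, ys = grid.cell_centers()
    targets = np.column_stack([xs.ravel(), ys.ravel()])
    rslr_pred, _ = krige_points(coords, vals, targets, fit_variogram(coords, vals))
    rslr_raster = Raster(grid, rslr_pred.reshape(grid.shape))
    write_ascii_grid(run / "rslr.asc", rslr_raster, fmt="%.3f")

    # --- summarize
    summaries = watershed_stats.zonal_summary(
        zsr, scene.watersheds, estuarine, rslr=rslr_raster)
    summaries = watershed_stats.screen_outliers(summaries)
    summary_frame = watershed_stats.summaries_to_frame(summaries)
    summary_frame.to_csv(run / "summaries.csv", index=False, float_format="%.6f")
    _write_manifest(run, "summarize",
                    ["zstar.asc", "zstar_sigma.asc", "rslr.asc",
                     "scene/watersheds.geojson"],
                    ["summaries.csv"], {})

    # --- trends
    model_frames = []
    residual_rows = []
    centroids = {wid: (geom.centroid.x, geom.centroid.y)
                 for wid, geom in scene.watersheds}
    for dependent in trend_models.DEPENDENTS:
        try:
            ranked = trend_models.fit_covariate_models(
                summary_frame, dependent,
                include_outliers=config.include_outliers,
                min_n=config.min_model_n,
            )
        except ValueError as exc:
            logger.warning("trend model for %s skipped: %s", dependent, exc)
            continue
        model_frames.append(trend_models.models_to_frame(ranked))
        best = ranked[0]
        frame = trend_models.prepare_model_frame(
            summary_frame, dependent, config.include_outliers)
        resid = np.asarray(best.fit.resid, dtype=float)
        xy = np.array([centroids[w] for w in frame["watershed_id"]])
        if len(resid) >= 5:
            spatial = trend_models.spatial_residual_model(resid, xy)
            residual_rows.append(
                {
                    "dependent": dependent,
                    "pseudo_r2": spatial.pseudo_r2,
                    "adj_r2_covariate": best.adj_r2,
                    "total_variance_explained_spatial":
                        spatial.total_variance_explained(best.adj_r2),
                    "variogram_family": spatial.variogram.family,
                    "variogram_nugget": spatial.variogram.nugget,
                    "variogram_partial_sill": spatial.variogram.partial_sill,
                    "variogram_range": spatial.variogram.range_,
                }
            )
    if model_frames:
        pd.concat(model_frames, ignore_index=True).to_csv(
            run / "models.csv", index=False, float_format="%.6f")
    if residual_rows:
        pd.DataFrame(residual_rows).to_csv(
            run / "residual_spatial.csv", index=False, float_format="%.6f")

    # --- tidal metrics from the gauge water-level series
    metric_rows = []
    metrics = []
    for gid, series in scene.water_levels.items():
        try:
            m = trend_models.compute_tidal_metrics(series)
        except ValueError as exc:
            logger.info("gauge %s excluded from tidal metrics: %s", gid, exc)
            continue
        metrics.append(m)
        metric_rows.append(
            {
                "gauge_id": gid, "msl": m.msl, "mhw": m.mhw, "mhhw": m.mhhw,
                "amplitude": m.amplitude, "dhq": m.dhq, "hat": m.hat,
                "hot": m.hot, "hat_star": m.hat_star, "hot_star": m.hot_star,
                "dhq_star": m.dhq_star,
                "rslr_mm_yr": rslr_by_gauge.get(gid, float("nan")),
            }
        )
    pd.DataFrame(metric_rows).to_csv(run / "tidal_metrics.csv", index=False,
                                     float_format="%.5f")
    if len(metrics) >= 3:
        trend_models.fit_tidal_metric_regressions(metrics).to_csv(
            run / "tidal_metric_models.csv", index=False, float_format="%.6f")
    _write_manifest(run, "trends",
                    ["summaries.csv", "scene/water_levels/"],
                    ["models.csv", "residual_spatial.csv", "tidal_metrics.csv",
                     "tidal_metric_models.csv"],
                    {"include_outliers": list(config.include_outliers)})

    return run


def checksum_run(run_dir: str | Path) -> dict[str, str]:
    """SHA-256 of every file in a run directory (for determinism checks)."""
    run = Path(run_dir)
    out = {}
    for path in sorted(run.rglob("*")):
        if path.is_file():
            out[str(path.relative_to(run))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    return out
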