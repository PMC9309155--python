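"""Zonal watershed summaries of relative tidal elevation.

Statistics are taken over estuarine-emergent area-of-interest pixels whose
cell centers fall inside each watershed polygon: mean, SD, median, the
2.5/25/75/97.5% quantiles (linear interpolation between order statistics),
min/max, plus medians of the uncertainty, tidal amplitude and RSLR layers.
Watersheds with anomalously high median Z* are flagged by the Tukey-style
rule median > Q75 + 1.5 IQR computed across watershed medians; flagged
units are excluded from trend modelling but retained in listings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .dem_prep import AoiMask
from .grid import Raster
from .zstar import ZStarRaster

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "watershed_id", "n_pixels", "mean", "sd", "median",
    "q2.5", "q25", "q75", "q97.5", "min", "max", "iqr",
    "median_sigma_zstar", "median_amplitude", "median_rslr", "outlier_flag",
]


@dataclass
class WatershedSummary:
    watershed_id: str
    n_pixels: int
    mean: float
    sd: float
    median: float
    q2_5: float
    q25: float
    q75: float
    q97_5: float
    min: float
    max: float
    median_sigma_zstar: float
    median_amplitude: float
    median_rslr: float = float("nan")
    outlier_flag: bool = False

    @property
    def iqr(self) -> float:
        return self.q75 - self.q25

    def as_row(self) -> dict:
        return {
            "watershed_id": self.watershed_id, "n_pixels": self.n_pixels,
            "mean": self.mean, "sd": self.sd, "median": self.median,
            "q2.5": self.q2_5, "q25": self.q25, "q75": self.q75,
            "q97.5": self.q97_5, "min": self.min, "max": self.max,
            "iqr": self.iqr, "median_sigma_zstar": self.median_sigma_zstar,
            "median_amplitude": self.median_amplitude,
            "median_rslr": self.median_rslr, "outlier_flag": self.outlier_flag,
        }


def summaries_to_frame(summaries: list[WatershedSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries], columns=SUMMARY_COLUMNS)


def pixels_in_polygon(
    raster: Raster, geometry: BaseGeometry, mask: np.ndarray | None = None
) -> np.ndarray:
    """Boolean selector of valid cells whose centers fall inside the polygon.

    Boundary cells belong to the polygon containing their center; when
    zones share a boundary, assignment order (lowest watershed id first)
    breaks ties deterministically in :func:`zonal_summary`.
    """
    if not geometry.is_valid:
        raise ValueError("invalid zone geometry")
    xs, ys = raster.grid.cell_centers()
    inside = shapely.contains_xy(geometry, xs, ys)
    sel = inside & raster.mask
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    return sel


def zonal_summary(
    zstar: ZStarRaster,
    zones: list[tuple[str, BaseGeometry]],
    class_mask: AoiMask | np.ndarray,
    rslr: Raster | None = None,
) -> list[WatershedSummary]:
    """Per-watershed summary of Z* over estuarine AOI pixels.

    Zones with no AOI pixels are omitted with a logged notice.  Cells
    claimed by more than one polygon go to the zone earliest in id order.
    """
    mask = class_mask.include if isinstance(class_mask, AoiMask) else np.asarray(class_mask, dtype=bool)
    taken = np.zeros(zstar.zstar.grid.shape, dtype=bool)
    out: list[WatershedSummary] = []
    for wid, geom in sorted(zones, key=lambda z: z[0]):
        if not geom.is_valid:
            raise ValueError(f"watershed {wid}: invalid geometry")
        sel = pixels_in_polygon(zstar.zstar, geom, mask) & ~taken
        taken |= sel
        n = int(sel.sum())
        if n == 0:
            logger.info("watershed %s has no AOI pixels; omitted", wid)
            continue
        vals = zstar.zstar.values[sel]
        q2_5, q25, med, q75, q97_5 = np.quantile(
            vals, [0.025, 0.25, 0.5, 0.75, 0.975])
        out.append(
            WatershedSummary(
                watershed_id=wid, n_pixels=n,
                mean=float(vals.mean()), sd=float(vals.std(ddof=1)) if n > 1 else 0.0,
                median=float(med), q2_5=float(q2_5), q25=float(q25),
                q75=float(q75), q97_5=float(q97_5),
                min=float(vals.min()), max=float(vals.max()),
                median_sigma_zstar=float(np.median(zstar.sigma.values[sel])),
                median_amplitude=float(np.median(zstar.amplitude.values[sel])),
                median_rslr=float(np.median(rslr.values[sel])) if rslr is not None else float("nan"),
            )
        )
    return out


def screen_outliers(summaries: list[WatershedSummary]) -> list[WatershedSummary]:
    """Flag watersheds whose median Z* exceeds Q75 + 1.5 IQR of the medians.

    Returns the same summaries with ``outlier_flag`` set; flagged units are
    excluded from the trend models downstream but kept in listings.
    """
    if len(summaries) < 4:
        logger.warning("fewer than 4 watersheds; outlier screen skipped")
        return summaries
    medians = np.array([s.median for s in summaries])
    q25, q75 = np.quantile(medians, [0.25, 0.75])
    cutoff = q75 + 1.5 * (q75 - q25)
    for s in summaries:
        s.outlier_flag = bool(s.median > cutoff)
    return summaries


def regional_rollup(
    area_table: pd.DataFrame, region_map: dict[str, str]
) -> pd.DataFrame:
    """Roll zone-level low/high area estimates up to regions.

    ``area_table`` needs columns zone, class ('low'|'high'), mean_ha,
    sd_ha.  Region SDs combine zone SDs in quadrature (independence across
    zones); the fraction-low column is mean low / (low + high).
    """
    unmapped = set(area_table["zone"]) - set(region_map)
    if unmapped:
        raise ValueError(f"zones without a region: {sorted(unmapped)}")
    tab = area_table.copy()
    tab["region"] = tab["zone"].map(region_map)
    rows = []
    for region, grp in tab.groupby("region", sort=True):
        low = grp[grp["class"] == "low"]
        high = grp[grp["class"] == "high"]
        mean_low = float(low["mean_ha"].sum())
        mean_high = float(high["mean_ha"].sum())
        se = float(np.sqrt((grp["sd_ha"] ** 2).sum()))
        total = mean_low + mean_high
        rows.append(
            {
                "region": region,
                "mean_low_ha": mean_low,
                "mean_high_ha": mean_high,
                "standard_error_ha": se,
                "fraction_low": mean_low / total if total > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
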