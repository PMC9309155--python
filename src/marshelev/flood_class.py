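"""Probabilistic low/high-elevation marsh classification and area estimation.

Per pixel, the distance of the mapped Z* from a threshold x (the MHW line,
x = 1) is expressed in units of the pixel's propagated uncertainty,
Z' = (x - Z*)/sigma_Z*, and converted to a probability of lying below the
threshold with the standard normal CDF.  Probability maps are stored at
two-decimal precision.  Area is then summarized by treating each stored
probability class as a binomial: mean area = sum n_i phi_i * pixel area,
variance = sum n_i phi_i (1 - phi_i) * pixel area^2 over the 0.00..1.00
classes.  The same machinery produces the probabilistic below-MHHWS layer
used for the area-of-interest rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .grid import NODATA, AnalysisGrid, Raster, check_aligned

logger = logging.getLogger(__name__)

#: hectares of one 30 m x 30 m cell
PIXEL_AREA_HA = 0.09


@dataclass
class ProbabilityRaster:
    """A per-pixel probability map stored at 0.01 precision."""

    p: Raster
    threshold_used: float = 1.0

    def __post_init__(self) -> None:
        vals = self.p.values[self.p.mask]
        if vals.size and ((vals < 0) | (vals > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")

    def complement(self) -> "ProbabilityRaster":
        """p_high = 1 - p_low, computed on the rounded values so the two
        classes sum to exactly 1 cellwise."""
        out = self.p.values.copy()
        m = self.p.mask
        out[m] = np.round(1.0 - out[m], 2)
        return ProbabilityRaster(self.p.copy_with(out), self.threshold_used)


def error_normalize(zstar: Raster, sigma: Raster, x: float = 1.0) -> Raster:
    """Z' = (x - Z*)/sigma_Z* cellwise; nodata propagates.

    Cells with sigma = 0 get signed infinity (probability 0 or 1
    downstream); logged.
    """
    grid = check_aligned(zstar, sigma)
    valid = zstar.mask & sigma.mask
    out = np.full(grid.shape, NODATA)
    s = sigma.values[valid]
    zs = zstar.values[valid]
    if np.any(s == 0):
        logger.warning("%d cells have sigma_Z* = 0; Z' set to signed infinity",
                       int((s == 0).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        zprime = (x - zs) / s
    zprime[(s == 0) & (zs == x)] = 0.0
    out[valid] = zprime
    return Raster(grid, out)


def prob_below(zprime: Raster, threshold_used: float = 1.0,
               decimals: int = 2) -> ProbabilityRaster:
    """Probability of lying below the threshold: Phi(Z'), rounded to 2 dp."""
    out = np.full(zprime.grid.shape, NODATA)
    m = zprime.mask
    out[m] = np.round(norm.cdf(zprime.values[m]), decimals)
    return ProbabilityRaster(Raster(zprime.grid, out), threshold_used)


def classify_binary(p_low: ProbabilityRaster) -> Raster:
    """Binary low(1)/high(0) map at the 50% boundary; ties (p = 0.50) go low."""
    out = np.full(p_low.p.grid.shape, NODATA)
    m = p_low.p.mask
    out[m] = (p_low.p.values[m] >= 0.5).astype(float)
    return Raster(p_low.p.grid, out)


@dataclass
class AreaEstimate:
    """Binomial mean/SD of class area, hectares."""

    mean_area: float
    sd_area: float
    n_pixels_by_bin: np.ndarray        # counts over classes 0.00 .. 1.00
    pixel_area: float = PIXEL_AREA_HA

    @property
    def n_pixels(self) -> int:
        return int(self.n_pixels_by_bin.sum())

    @property
    def total_area(self) -> float:
        return self.n_pixels * self.pixel_area


def binomial_area(
    p_raster: ProbabilityRaster,
    pixel_area: float = PIXEL_AREA_HA,
    mask: np.ndarray | None = None,
) -> AreaEstimate:
    """Binomial area estimate over the stored probability classes.

    Pixels are grouped by their 2-dp probability value phi_i = i/100,
    i = 0..100; mean = sum n_i phi_i * pixel_area and
    variance = sum n_i phi_i (1 - phi_i) * pixel_area^2.
    """
    m = p_raster.p.mask
    if mask is not None:
        m = m & np.asarray(mask, dtype=bool)
    p = p_raster.p.values[m]
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities outside [0, 1]")
    idx = np.round(p * 100).astype(int)
    counts = np.bincount(idx, minlength=101).astype(float)
    phi = np.arange(101) / 100.0
    mean = float((counts * phi).sum() * pixel_area)
    var = float((counts * phi * (1.0 - phi)).sum() * pixel_area**2)
    return AreaEstimate(mean, float(np.sqrt(var)), counts, pixel_area)


def unbinned_area(
    p: np.ndarray, pixel_area: float = PIXEL_AREA_HA
) -> tuple[float, float]:
    """Unbinned oracle: per-pixel Bernoulli sum without probability classes."""
    p = np.asarray(p, dtype=float)
    mean = float(p.sum() * pixel_area)
    sd = float(np.sqrt((p * (1.0 - p)).sum()) * pixel_area)
    return mean, sd
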