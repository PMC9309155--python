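"""Dimensionless tidal elevation Z*_MHW and first-order error propagation.

Z*_MHW = (Z - MSL) / (MHW - MSL) places a ground elevation Z within the
local tidal frame: 0 at mean sea level, 1 at mean high water.  Marsh below
the MHW line floods roughly twice daily (low-elevation marsh); marsh above
it floods once daily or less (high-elevation marsh).

The propagated standard deviation of Z* combines three error sources by a
first-order Taylor expansion:

    sigma_Z*^2 = (dZ*/dZ)^2 sigma_Z^2
               + (dZ*/dMHW)^2 sigma_MHW^2
               + (dZ*/dMSL)^2 sigma_MSL^2
               + 2 (dZ*/dMHW)(dZ*/dMSL) sigma_MHW sigma_MSL rho2

with dZ*/dZ = 1/A, dZ*/dMHW = -(Z-MSL)/A^2, dZ*/dMSL = (Z-MHW)/A^2 where
A = MHW - MSL.  Elevation error is taken independent of the datum errors;
MHW and MSL errors are correlated (rho2, 0.873 for the national gauge
network) because both datums come from the same gauges.

``as_printed=True`` drops the minus sign on dZ*/dMHW, reproducing a
published variant of the MHW partial; squared terms are unaffected but
the covariance cross term flips sign.  The default keeps the
mathematically correct derivatives: an error that moves MHW and MSL
together must inflate, not deflate, the variance of Z* for elevations
inside the tidal frame (confirmed by Monte-Carlo sampling in the test
suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import NODATA, Raster, check_aligned


@dataclass(frozen=True)
class ErrorBudget:
    """Pixel-level elevation error components, metres.

    sigma_random is per-pixel LiDAR random error; sigma_bias is the
    site-level standard error of the single national vegetation bias
    correction.  They add in quadrature to the total elevation
    uncertainty sigma_z (0.233 m with the default components).
    """

    sigma_random: float = 0.205
    sigma_bias: float = 0.110
    rho2: float = 0.873

    def __post_init__(self) -> None:
        if self.sigma_random < 0 or self.sigma_bias < 0:
            raise ValueError("error components must be nonnegative")
        if not abs(self.rho2) <= 1:
            raise ValueError("|rho2| must be <= 1")

    @property
    def sigma_z(self) -> float:
        return total_elevation_sigma(self.sigma_random, self.sigma_bias)


def total_elevation_sigma(sigma_random: float, sigma_bias: float) -> float:
    """Quadrature sum of random and bias elevation error components."""
    if sigma_random < 0 or sigma_bias < 0:
        raise ValueError("error components must be nonnegative")
    return float(np.hypot(sigma_random, sigma_bias))


def compute_zstar(z, msl, mhw):
    """Elementwise Z* = (z - msl) / (mhw - msl); requires mhw > msl."""
    z = np.asarray(z, dtype=float)
    msl = np.asarray(msl, dtype=float)
    mhw = np.asarray(mhw, dtype=float)
    amp = mhw - msl
    if np.any(amp <= 0):
        bad = np.argwhere(np.atleast_1d(amp) <= 0)[0]
        raise ValueError(f"MHW <= MSL at cell index {tuple(bad)}")
    return (z - msl) / amp


def zstar_partials(z, msl, mhw, as_printed: bool = False):
    """Partial derivatives (dZ*/dZ, dZ*/dMHW, dZ*/dMSL)."""
    z = np.asarray(z, dtype=float)
    msl = np.asarray(msl, dtype=float)
    mhw = np.asarray(mhw, dtype=float)
    amp = mhw - msl
    d_z = 1.0 / amp
    d_mhw = (z - msl) / amp**2 if as_printed else -(z - msl) / amp**2
    d_msl = (z - mhw) / amp**2
    return d_z, d_mhw, d_msl


def propagate_zstar_sigma(
    z, msl, mhw,
    sigma_z, sigma_msl, sigma_mhw,
    rho2: float = 0.873,
    as_printed: bool = False,
):
    """First-order standard deviation of Z*.

    All elevation arguments in metres; broadcasting applies.  Raises if a
    propagated variance comes out negative (an invalid rho2/sign
    configuration).
    """
    if not abs(rho2) <= 1:
        raise ValueError("|rho2| must be <= 1")
    sigma_z = np.asarray(sigma_z, dtype=float)
    sigma_msl = np.asarray(sigma_msl, dtype=float)
    sigma_mhw = np.asarray(sigma_mhw, dtype=float)
    if np.any(sigma_z < 0) or np.any(sigma_msl < 0) or np.any(sigma_mhw < 0):
        raise ValueError("standard deviations must be nonnegative")
    d_z, d_mhw, d_msl = zstar_partials(z, msl, mhw, as_printed=as_printed)
    var = (
        d_z**2 * sigma_z**2
        + d_mhw**2 * sigma_mhw**2
        + d_msl**2 * sigma_msl**2
        + 2.0 * d_mhw * d_msl * sigma_mhw * sigma_msl * rho2
    )
    if np.any(var < 0):
        raise ValueError("negative propagated variance; check rho2 and partial signs")
    return np.sqrt(var)


@dataclass
class ZStarRaster:
    """Per-pixel Z*, its propagated sigma, and the tidal amplitude layer."""

    zstar: Raster
    sigma: Raster
    amplitude: Raster

    def __post_init__(self) -> None:
        check_aligned(self.zstar, self.sigma, self.amplitude)


def compute_zstar_raster(
    dem: Raster,
    msl: Raster,
    mhw: Raster,
    se_msl: Raster,
    se_mhw: Raster,
    budget: ErrorBudget = ErrorBudget(),
    as_printed: bool = False,
) -> ZStarRaster:
    """Z* and sigma_Z* over aligned rasters; nodata propagates, never zero-fills.

    Elevation uncertainty is applied as the spatial constant
    ``budget.sigma_z``; the datum SE layers vary per pixel.
    """
    grid = check_aligned(dem, msl, mhw, se_msl, se_mhw)
    valid = dem.mask & msl.mask & mhw.mask & se_msl.mask & se_mhw.mask

    amp_all = mhw.values - msl.values
    if np.any(amp_all[valid] <= 0):
        bad = np.argwhere(valid & (amp_all <= 0))[0]
        raise ValueError(f"MHW <= MSL at grid cell {tuple(bad)}")

    zs = np.full(grid.shape, NODATA)
    sg = np.full(grid.shape, NODATA)
    amp = np.full(grid.shape, NODATA)
    zs[valid] = compute_zstar(dem.values[valid], msl.values[valid], mhw.values[valid])
    sg[valid] = propagate_zstar_sigma(
        dem.values[valid], msl.values[valid], mhw.values[valid],
        budget.sigma_z, se_msl.values[valid], se_mhw.values[valid],
        rho2=budget.rho2, as_printed=as_printed,
    )
    amp[valid] = amp_all[valid]
    return ZStarRaster(
        Raster(grid, zs), Raster(grid, sg), Raster(grid, amp)
    )
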