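"""Tidal datum surfaces from a gauge network.

Datum values (MSL, MHW, MHHW, MHHWS relative to NAVD88) are spread from
tide gauges to the analysis grid by ordinary kriging with a variogram
fitted by weighted least squares; datum standard errors are spread by
inverse distance weighting, and the two uncertainty sources — datum
quality and spatial extrapolation — combine in quadrature, being driven
by different things (record completeness vs distance from gauge).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .grid import AnalysisGrid, Raster, check_aligned

logger = logging.getLogger(__name__)

DATUM_NAMES = ("msl", "mhw", "mhhw", "mhhws")


@dataclass
class GaugeRecord:
    """One tide gauge: datum values and standard errors relative to NAVD88."""

    gauge_id: str
    x: float
    y: float
    msl: float
    mhw: float
    mhhw: float
    mhhws: float
    se_msl: float
    se_mhw: float
    se_mhhw: float
    se_mhhws: float
    epoch: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.mhw > self.msl:
            raise ValueError(f"gauge {self.gauge_id}: MHW must exceed MSL")
        if self.mhhw < self.mhw:
            raise ValueError(f"gauge {self.gauge_id}: MHHW must be >= MHW")
        for name in ("se_msl", "se_mhw", "se_mhhw", "se_mhhws"):
            if getattr(self, name) < 0:
                raise ValueError(f"gauge {self.gauge_id}: {name} must be >= 0")

    def datum(self, which: str) -> float:
        return getattr(self, which)

    def se(self, which: str) -> float:
        return getattr(self, f"se_{which}")

    @property
    def amplitude(self) -> float:
        """Tidal amplitude MHW - MSL, metres."""
        return self.mhw - self.msl


# ---------------------------------------------------------------------------
# Variogram

_FAMILIES = ("exponential", "spherical", "gaussian")


@dataclass
class VariogramModel:
    """Isotropic semivariogram gamma(h) = nugget + partial_sill * f(h/range)."""

    family: str = "exponential"
    nugget: float = 0.0
    partial_sill: float = 1.0
    range_: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValueError("variogram parameters out of range")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        r = self.range_
        if self.family == "exponential":
            f = 1.0 - np.exp(-3.0 * h / r)
        elif self.family == "gaussian":
            f = 1.0 - np.exp(-3.0 * (h / r) ** 2)
        else:  # spherical
            u = np.clip(h / r, 0.0, 1.0)
            f = 1.5 * u - 0.5 * u**3
        gamma = self.nugget + self.partial_sill * f
        # gamma(0) = 0 by definition; the nugget is a limit from the right
        return np.where(h == 0.0, 0.0, gamma)

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill


def empirical_variogram(
    coords: np.ndarray, values: np.ndarray, n_bins: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariance to half the maximum pairwise distance.

    Returns (bin center distances, semivariances, pair counts); empty bins
    are dropped.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    d = cdist(coords, coords)
    iu = np.triu_indices(len(values), k=1)
    h = d[iu]
    sq = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    h_max = h.max() / 2.0
    edges = np.linspace(0.0, h_max, n_bins + 1)
    which = np.digitize(h, edges[1:-1])
    keep = h <= h_max
    centers, gammas, counts = [], [], []
    for b in range(n_bins):
        sel = keep & (which == b)
        if sel.sum() == 0:
            continue
        centers.append(h[sel].mean())
        gammas.append(sq[sel].mean())
        counts.append(sel.sum())
    return np.array(centers), np.array(gammas), np.array(counts)


def fit_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    family: str = "exponential",
    n_bins: int = 10,
) -> VariogramModel:
    """WLS variogram fit (weights = pair counts) to the empirical cloud.

    Degenerate inputs (constant values, too few pairs) fall back to a
    near-flat variogram so kriging remains solvable.
    """
    h, gamma, n = empirical_variogram(coords, values, n_bins=n_bins)
    var = float(np.var(values))
    h_scale = float(np.max(cdist(coords, coords)))
    if len(h) < 3 or var <= 0 or not np.any(gamma > 0):
        return VariogramModel(family, nugget=0.0, partial_sill=max(var, 1e-12),
                              range_=max(h_scale / 2.0, 1e-6))

    def resid(theta: np.ndarray) -> np.ndarray:
        nugget, psill, rng = theta
        model = VariogramModel(family, nugget, psill, rng)
        return np.sqrt(n) * (model(h) - gamma)

    x0 = np.array([0.0, var, h_scale / 2.0])
    lb = np.array([0.0, 1e-12, 1e-6])
    ub = np.array([max(gamma.max(), 1e-9), 10 * max(gamma.max(), var), 10 * h_scale])
    sol = least_squares(resid, np.clip(x0, lb, ub), bounds=(lb, ub))
    nugget, psill, rng = sol.x
    return VariogramModel(family, float(nugget), float(psill), float(rng))


# ---------------------------------------------------------------------------
# Ordinary kriging

def kriging_system(
    coords: np.ndarray, variogram: VariogramModel
) -> np.ndarray:
    """LHS matrix of the ordinary kriging equations (semivariogram form)."""
    n = len(coords)
    gamma = variogram(cdist(coords, coords))
    lhs = np.empty((n + 1, n + 1))
    lhs[:n, :n] = gamma
    lhs[:n, n] = 1.0
    lhs[n, :n] = 1.0
    lhs[n, n] = 0.0
    return lhs


def krige_points(
    coords: np.ndarray,
    values: np.ndarray,
    targets: np.ndarray,
    variogram: VariogramModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary kriging prediction and standard error at target points.

    Exact interpolator: at a gauge location the prediction equals the gauge
    value and the standard error is zero.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.asarray(targets, dtype=float)
    n = len(coords)
    if n < 1:
        raise ValueError("kriging needs at least one gauge")
    if len(np.unique(coords, axis=0)) != n:
        dup = [i for i in range(n) if (coords == coords[i]).all(1).sum() > 1]
        raise ValueError(f"duplicate gauge coordinates at indices {dup}")

    lhs = kriging_system(coords, variogram)
    try:
        lu = np.linalg.inv(lhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular kriging system") from exc

    g0 = variogram(cdist(targets, coords))             # (m, n)
    rhs = np.hstack([g0, np.ones((len(targets), 1))])  # (m, n+1)
    lam = rhs @ lu.T                                   # (m, n+1)
    pred = lam[:, :n] @ values
    var = np.einsum("ij,ij->i", lam, rhs)
    var = np.maximum(var, 0.0)
    return pred, np.sqrt(var)


def idw_points(
    coords: np.ndarray,
    values: np.ndarray,
    targets: np.ndarray,
    power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation; exact at data points."""
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if len(coords) == 0:
        raise ValueError("IDW needs at least one gauge")
    d = cdist(targets, coords)
    out = np.empty(len(targets))
    at_gauge = d == 0.0
    hit = at_gauge.any(axis=1)
    if hit.any():
        out[hit] = values[np.argmax(at_gauge[hit], axis=1)]
    free = ~hit
    if free.any():
        w = d[free] ** (-power)
        out[free] = (w @ values) / w.sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# Datum fields

@dataclass
class DatumField:
    """A datum surface with its kriging, datum and total SE layers (metres)."""

    value: Raster
    se_kriging: Raster
    se_datum: Raster
    se_total: Raster
    variogram: VariogramModel | None = None

    def __post_init__(self) -> None:
        check_aligned(self.value, self.se_kriging, self.se_datum, self.se_total)


def krige_datum(
    gauges: list[GaugeRecord],
    which_datum: str,
    grid: AnalysisGrid,
    variogram: VariogramModel | None = None,
) -> tuple[Raster, Raster, VariogramModel]:
    """Krige one datum from the gauge network onto the grid.

    Returns (value raster, kriging-SE raster, fitted variogram).
    """
    if which_datum not in DATUM_NAMES:
        raise ValueError(f"unknown datum {which_datum!r}")
    if len(gauges) < 3:
        raise ValueError("kriging a datum needs at least 3 gauges")
    coords = np.array([[g.x, g.y] for g in gauges])
    values = np.array([g.datum(which_datum) for g in gauges])
    if variogram is None:
        variogram = fit_variogram(coords, values)
    xs, ys = grid.cell_centers()
    targets = np.column_stack([xs.ravel(), ys.ravel()])
    pred, se = krige_points(coords, values, targets, variogram)
    return (
        Raster(grid, pred.reshape(grid.shape)),
        Raster(grid, se.reshape(grid.shape)),
        variogram,
    )


def idw_error(
    gauges: list[GaugeRecord],
    which_se: str,
    grid: AnalysisGrid,
    power: float = 2.0,
) -> Raster:
    """IDW surface of one datum's reported standard error."""
    if which_se not in DATUM_NAMES:
        raise ValueError(f"unknown datum {which_se!r}")
    coords = np.array([[g.x, g.y] for g in gauges])
    values = np.array([g.se(which_se) for g in gauges])
    xs, ys = grid.cell_centers()
    targets = np.column_stack([xs.ravel(), ys.ravel()])
    out = idw_points(coords, values, targets, power=power)
    return Raster(grid, out.reshape(grid.shape))


def interpolate_datum(
    gauges: list[GaugeRecord],
    which: str,
    grid: AnalysisGrid,
    power: float = 2.0,
    variogram: VariogramModel | None = None,
) -> DatumField:
    """Full datum field: kriged value, IDW datum SE, quadrature total SE."""
    value, se_krig, vgm = krige_datum(gauges, which, grid, variogram=variogram)
    se_dat = idw_error(gauges, which, grid, power=power)
    se_total = Raster(grid, np.sqrt(se_dat.values**2 + se_krig.values**2))
    return DatumField(value, se_krig, se_dat, se_total, vgm)


def compose_transformation_error(
    se_a: np.ndarray, se_b: np.ndarray, rho: float
) -> np.ndarray:
    """Standard error of a sum of two correlated datum transformations.

    sigma_c = sqrt(sigma_a^2 + sigma_b^2 + 2 rho sigma_a sigma_b); used for
    chained datum offsets (e.g. MHHWS relative to MHHW on top of MHHW
    relative to NAVD88, correlation 0.716 in the national gauge network).
    """
    if not abs(rho) <= 1:
        raise ValueError("|rho| must be <= 1")
    a = np.asarray(se_a, dtype=float)
    b = np.asarray(se_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("standard errors must be nonnegative")
    return np.sqrt(a**2 + b**2 + 2.0 * rho * a * b)


# ---------------------------------------------------------------------------
# Gauge table I/O

GAUGE_COLUMNS = [
    "id", "x", "y", "msl", "mhw", "mhhw", "mhhws",
    "se_msl", "se_mhw", "se_mhhw", "se_mhhws", "date_min",
]


def gauges_to_frame(gauges: list[GaugeRecord]):
    import pandas as pd

    rows = [
        {
            "id": g.gauge_id, "x": g.x, "y": g.y,
            "msl": g.msl, "mhw": g.mhw, "mhhw": g.mhhw, "mhhws": g.mhhws,
            "se_msl": g.se_msl, "se_mhw": g.se_mhw,
            "se_mhhw": g.se_mhhw, "se_mhhws": g.se_mhhws,
            "date_min": g.epoch,
        }
        for g in gauges
    ]
    return pd.DataFrame(rows, columns=GAUGE_COLUMNS)


def gauges_from_frame(frame) -> list[GaugeRecord]:
    return [
        GaugeRecord(
            gauge_id=str(r["id"]), x=float(r["x"]), y=float(r["y"]),
            msl=float(r["msl"]), mhw=float(r["mhw"]),
            mhhw=float(r["mhhw"]), mhhws=float(r["mhhws"]),
            se_msl=float(r["se_msl"]), se_mhw=float(r["se_mhw"]),
            se_mhhw=float(r["se_mhhw"]), se_mhhws=float(r["se_mhhws"]),
            epoch=str(r["date_min"]),
        )
        for _, r in frame.iterrows()
    ]
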