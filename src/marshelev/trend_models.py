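"""Geographic trend models for watershed-level relative elevation.

Watershed median Z*, Z* variability (interquartile range) and Z*
uncertainty are modelled against tidal amplitude (MHW - MSL) and relative
sea-level rise (RSLR).  Candidate covariate models are every submodel of
{log amplitude, RSLR, interaction} respecting marginality, ranked by AICc;
effect sizes per term are omega-squared from sequential ANOVA.  Amplitude,
IQR and uncertainty are natural-log transformed.  Z* uncertainty is
modelled by simple regression on log amplitude only: with a constant
elevation error budget sigma_Z* scales as sigma_Z / amplitude, so the
expected log-log slope is -1.

The residuals of the selected covariate model are then given a spatial
model: a semivariogram over watershed centroids with leave-one-out
ordinary kriging, summarized by a pseudo-R^2 of the out-of-fold
predictions.  Tide-gauge water level series provide RSLR (OLS slope of
monthly means on fractional year) and the tidal metrics HAT, HOT and DHQ
used to probe what caps marsh elevation in the tidal frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .datum_fields import VariogramModel, fit_variogram, krige_points
from .synthetic_scene import WaterLevelSeries

logger = logging.getLogger(__name__)

DEPENDENTS = ("median_zstar", "log_iqr", "log_sigma")


class IncompleteRecordError(ValueError):
    """Water-level record too incomplete for a trend estimate."""


# ---------------------------------------------------------------------------
# Relative sea-level rise

def estimate_rslr(
    monthly: pd.DataFrame,
    window: tuple[int, int] = (1983, 2001),
    min_completeness: float = 0.66,
) -> float:
    """RSLR (mm/yr): OLS slope of monthly mean level on fractional year.

    ``monthly`` needs columns ``timestamp`` and ``level_mm``.  Gauges with
    less than ``min_completeness`` of the window's months present are
    rejected with :class:`IncompleteRecordError`.
    """
    ts = pd.to_datetime(monthly["timestamp"])
    y0, y1 = window
    in_win = (ts.dt.year >= y0) & (ts.dt.year <= y1)
    sub = monthly[in_win]
    n_months = 12 * (y1 - y0 + 1)
    have = pd.PeriodIndex(ts[in_win], freq="M").nunique()
    if have / n_months < min_completeness:
        raise IncompleteRecordError(
            f"record covers {have}/{n_months} months "
            f"({have / n_months:.0%} < {min_completeness:.0%})"
        )
    t = pd.to_datetime(sub["timestamp"])
    frac_year = t.dt.year + (t.dt.dayofyear - 0.5) / 365.25
    X = sm.add_constant(np.asarray(frac_year, dtype=float))
    fit = sm.OLS(np.asarray(sub["level_mm"], dtype=float), X).fit()
    return float(fit.params[1])


def monthly_means_from_series(series: WaterLevelSeries) -> pd.DataFrame:
    """Collapse a high-frequency series to monthly means in millimetres."""
    frame = series.to_frame().set_index("timestamp")
    monthly = frame["level_m"].resample("MS").mean() * 1000.0
    return monthly.rename("level_mm").reset_index()


# ---------------------------------------------------------------------------
# Tidal metrics

@dataclass
class TidalMetrics:
    """Custom tidal datums and derived flooding metrics for one gauge."""

    gauge_id: str
    msl: float
    mhw: float
    mhhw: float
    mhhws: float
    hat: float
    hot: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("tidal amplitude must be positive")
        if self.dhq < -1e-9:
            raise ValueError("MHHW below MHW")

    @property
    def amplitude(self) -> float:
        return self.mhw - self.msl

    @property
    def dhq(self) -> float:
        """Diurnal high tide inequality MHHW - MHW, metres."""
        return self.mhhw - self.mhw

    @property
    def hat_star(self) -> float:
        return (self.hat - self.msl) / self.amplitude

    @property
    def hot_star(self) -> float:
        return (self.hot - self.msl) / self.amplitude

    @property
    def dhq_star(self) -> float:
        return self.dhq / self.amplitude


def compute_tidal_metrics(
    series: WaterLevelSeries,
    min_separation_hours: float = 10.0,
    min_highs_per_year: int = 300,
) -> TidalMetrics:
    """Recompute tidal datums from a water-level series.

    MSL is the series mean; high tides are local maxima separated by at
    least ``min_separation_hours``; MHW is the mean of all highs, MHHW the
    mean of daily highest highs, MHHWS the mean of monthly maximum highs.
    HOT is the highest observed level; HAT is the maximum of the noise-free
    constituent reconstruction when the series carries constituents, else
    HOT.
    """
    step_h = (series.times[1] - series.times[0]).total_seconds() / 3600.0
    span_years = len(series.times) * step_h / (24 * 365.25)
    if span_years < 1.0 - 1e-9 or step_h > 1.0:
        raise ValueError("series must span >= 1 year at <= 1 h resolution")
    distance = max(int(round(min_separation_hours / step_h)), 1)
    peaks, _ = find_peaks(series.level_m, distance=distance)
    if len(peaks) / span_years < min_highs_per_year:
        raise ValueError(
            f"only {len(peaks)} highs detected in {span_years:.1f} yr; not tidal"
        )
    highs = pd.Series(series.level_m[peaks], index=series.times[peaks])
    msl = float(series.level_m.mean())
    mhw = float(highs.mean())
    mhhw = float(highs.resample("D").max().dropna().mean())
    mhhws = float(highs.resample("MS").max().dropna().mean())
    hot = float(series.level_m.max())
    if series.constituents:
        # dense evaluation of the astronomic signal for the HAT analog
        t_dense = np.arange(0.0, len(series.times) * step_h, step_h / 10.0)
        hat = float(series.astronomic_level(t_dense).max())
    else:
        hat = hot
    return TidalMetrics(series.gauge_id, msl, mhw, mhhw, mhhws, hat, hot)


def fit_tidal_metric_regressions(metrics: list[TidalMetrics]) -> pd.DataFrame:
    """Regress log tidal amplitude on each starred metric across gauges.

    Returns one row per metric (HAT*, HOT*, log DHQ*) with slope, p-value
    and R^2; negative slopes indicate the metric shrinks as tidal
    amplitude widens.
    """
    tab = pd.DataFrame(
        {
            "log_amplitude": [np.log(m.amplitude) for m in metrics],
            "hat_star": [m.hat_star for m in metrics],
            "hot_star": [m.hot_star for m in metrics],
            "log_dhq_star": [np.log(m.dhq_star) if m.dhq_star > 0 else np.nan
                             for m in metrics],
        }
    )
    rows = []
    for col in ("hat_star", "hot_star", "log_dhq_star"):
        sub = tab[["log_amplitude", col]].dropna()
        fit = smf.ols(f"log_amplitude ~ {col}", data=sub).fit()
        rows.append(
            {
                "metric": col,
                "slope": float(fit.params[col]),
                "p_value": float(fit.pvalues[col]),
                "r_squared": float(fit.rsquared),
                "n": int(fit.nobs),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Covariate models

_CANDIDATES = (
    (),
    ("log_amplitude",),
    ("rslr",),
    ("log_amplitude", "rslr"),
    ("log_amplitude", "rslr", "log_amplitude:rslr"),
)


@dataclass
class CovariateModelResult:
    """One fitted candidate model with its selection statistics."""

    dependent: str
    terms: tuple[str, ...]
    n: int
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    adj_r2: float
    aicc: float
    omega_squared: dict[str, float]
    p_value: float
    fit: object = field(repr=False)

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"y ~ {rhs}"

    def summary(self):
        return self.fit.summary()


def aicc_from_fit(fit, k: int | None = None) -> float:
    """AICc = AIC + 2k(k+1)/(n-k-1), k counting coefficients + residual variance."""
    n = int(fit.nobs)
    if k is None:
        k = int(fit.df_model) + 2  # slopes + intercept + sigma^2
    aic = -2.0 * fit.llf + 2.0 * k
    if n - k - 1 <= 0:
        return float("inf")
    return float(aic + 2.0 * k * (k + 1) / (n - k - 1))


def _omega_squared(fit, terms: tuple[str, ...]) -> dict[str, float]:
    """Per-term omega^2 from sequential (type-I) sums of squares."""
    if not terms:
        return {}
    tab = anova_lm(fit, typ=1)
    ms_err = float(tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"])
    ss_total = float(tab["sum_sq"].sum())
    out = {}
    for term in terms:
        row = tab.loc[term]
        om = (float(row["sum_sq"]) - float(row["df"]) * ms_err) / (ss_total + ms_err)
        out[term] = om
    return out


def prepare_model_frame(
    summaries: pd.DataFrame,
    dependent: str,
    include_outliers: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Model frame with y, log_amplitude and rslr from a summary table.

    Outlier-flagged watersheds are dropped unless on the include-list;
    watersheds whose log transform is undefined (IQR = 0 etc.) are dropped
    with a logged notice.
    """
    if dependent not in DEPENDENTS:
        raise ValueError(f"unknown dependent {dependent!r}")
    tab = summaries.copy()
    if "outlier_flag" in tab:
        drop = tab["outlier_flag"].astype(bool) & ~tab["watershed_id"].isin(include_outliers)
        tab = tab[~drop]
    with np.errstate(divide="ignore", invalid="ignore"):
        if dependent == "median_zstar":
            y = tab["median"].astype(float)
        elif dependent == "log_iqr":
            y = np.log(tab["iqr"].astype(float))
        else:
            y = np.log(tab["median_sigma_zstar"].astype(float))
        frame = pd.DataFrame(
            {
                "watershed_id": tab["watershed_id"],
                "y": y,
                "log_amplitude": np.log(tab["median_amplitude"].astype(float)),
                "rslr": tab["median_rslr"].astype(float),
            }
        )
    bad = ~np.isfinite(frame["y"]) | ~np.isfinite(frame["log_amplitude"])
    if dependent != "log_sigma":
        bad |= ~np.isfinite(frame["rslr"])
    if bad.any():
        logger.info("dropping %d watersheds with non-finite transforms", int(bad.sum()))
    return frame[~bad].reset_index(drop=True)


def fit_covariate_models(
    summaries: pd.DataFrame,
    dependent: str,
    include_outliers: tuple[str, ...] = (),
    min_n: int = 10,
) -> list[CovariateModelResult]:
    """Fit and AICc-rank candidate models for one dependent variable.

    For ``median_zstar`` and ``log_iqr`` every submodel of {log amplitude,
    RSLR, interaction} respecting marginality is fitted; ``log_sigma`` gets
    a simple regression on log amplitude only.  Results are sorted by AICc,
    best first.
    """
    frame = prepare_model_frame(summaries, dependent, include_outliers)
    n = len(frame)
    if n < min_n:
        raise ValueError(f"only {n} usable watersheds; need >= {min_n}")
    candidates = ((("log_amplitude",)),) if dependent == "log_sigma" else _CANDIDATES
    if dependent == "log_sigma":
        candidates = (("log_amplitude",),)
    results = []
    for terms in candidates:
        rhs = " + ".join(terms) if terms else "1"
        fit = smf.ols(f"y ~ {rhs}", data=frame).fit()
        results.append(
            CovariateModelResult(
                dependent=dependent,
                terms=terms,
                n=n,
                params=fit.params,
                bse=fit.bse,
                conf_int=fit.conf_int(),
                adj_r2=float(fit.rsquared_adj) if terms else 0.0,
                aicc=aicc_from_fit(fit),
                omega_squared=_omega_squared(fit, terms),
                p_value=float(fit.f_pvalue) if terms else float("nan"),
                fit=fit,
            )
        )
    results.sort(key=lambda r: r.aicc)
    return results


def models_to_frame(results: list[CovariateModelResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "dependent": r.dependent,
            "formula": r.formula,
            "n": r.n,
            "aicc": r.aicc,
            "adj_r2": r.adj_r2,
            "p_value": r.p_value,
        }
        for name, val in r.params.items():
            row[f"coef[{name}]"] = val
        for name, val in r.omega_squared.items():
            row[f"omega2[{name}]"] = val
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spatial residual model

@dataclass
class SpatialResidualResult:
    variogram: VariogramModel
    loo_predictions: np.ndarray
    residuals: np.ndarray
    pseudo_r2: float

    def total_variance_explained(self, adj_r2_covariate: float) -> float:
        """Share of total variance captured spatially:
        (1 - adj R^2 of the covariate model) x residual pseudo-R^2."""
        return (1.0 - adj_r2_covariate) * self.pseudo_r2


def pseudo_r2(observed: np.ndarray, predicted: np.ndarray,
              fold_means: np.ndarray) -> float:
    """1 - sum((x_i - y_i)^2) / sum((x_i - ybar_fold)^2)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    fold_means = np.asarray(fold_means, dtype=float)
    denom = float(((observed - fold_means) ** 2).sum())
    if denom == 0:
        return 0.0
    return 1.0 - float(((observed - predicted) ** 2).sum()) / denom


def spatial_residual_model(
    residuals: np.ndarray, coords: np.ndarray
) -> SpatialResidualResult:
    """Leave-one-out kriging of covariate-model residuals.

    For each watershed the semivariogram is refitted to the remaining
    units and an ordinary-kriging prediction made at the held-out
    centroid; pseudo-R^2 compares those predictions against per-fold
    calibration means.  A degenerate variogram (all residuals equal)
    reports pseudo-R^2 = 0.
    """
    residuals = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(residuals)
    if n < 5:
        raise ValueError("need at least 5 watersheds for the spatial model")
    if np.allclose(residuals, residuals[0]):
        logger.warning("all residuals equal; degenerate variogram, pseudo-R2 = 0")
        vgm = VariogramModel("exponential", 0.0, 1e-12, 1.0)
        return SpatialResidualResult(vgm, residuals.copy(), residuals.copy(), 0.0)

    preds = np.empty(n)
    fold_means = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        vgm_i = fit_variogram(coords[keep], residuals[keep])
        pred, _ = krige_points(coords[keep], residuals[keep],
                               coords[i][None, :], vgm_i)
        preds[i] = pred[0]
        fold_means[i] = residuals[keep].mean()
    vgm_full = fit_variogram(coords, residuals)
    return SpatialResidualResult(
        vgm_full, preds, residuals.copy(),
        pseudo_r2(residuals, preds, fold_means),
    )


# ---------------------------------------------------------------------------
# Synthetic watershed tables for trend-model validation

def synthesize_watershed_table(
    n: int,
    beta0: float,
    beta1: float,
    noise_sd: float,
    seed: int,
    amplitude_range: tuple[float, float] = (0.6, 2.4),
    rslr_range: tuple[float, float] = (2.0, 9.0),
    sigma_z: float = 0.233,
) -> pd.DataFrame:
    """Synthetic watershed summary table with a known amplitude trend.

    Median Z* follows beta0 + beta1 * ln(amplitude) + Normal(0, noise_sd);
    the uncertainty column follows the analytic sigma_z / amplitude law and
    IQR shrinks with amplitude.  Used for parameter-recovery checks on the
    covariate models.
    """
    rng = np.random.default_rng(seed)
    amp = np.exp(rng.uniform(np.log(amplitude_range[0]),
                             np.log(amplitude_range[1]), n))
    rslr = rng.uniform(*rslr_range, n)
    median = beta0 + beta1 * np.log(amp) + rng.normal(0.0, noise_sd, n)
    iqr = np.exp(-0.5 * np.log(amp) + rng.normal(0.0, 0.2, n))
    return pd.DataFrame(
        {
            "watershed_id": [f"ws{i:03d}" for i in range(n)],
            "n_pixels": np.full(n, 1000),
            "median": median,
            "iqr": iqr,
            "median_sigma_zstar": sigma_z / amp,
            "median_amplitude": amp,
            "median_rslr": rslr,
            "outlier_flag": np.zeros(n, dtype=bool),
        }
    )
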