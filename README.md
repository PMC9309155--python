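# marshelev

Relative tidal marsh elevation mapping with fully propagated uncertainty.

Tidal wetlands keep pace with sea-level rise by trapping sediment and
building root mass, and how much room a marsh has left in the tidal frame
is one of the simplest synoptic indicators of its resilience.  `marshelev`
computes the dimensionless tidal elevation

```
Z*_MHW = (Z − MSL) / (MHW − MSL)
```

on a raster grid — 0 at mean sea level, 1 at mean high water — from
elevation tiles (LiDAR-derived DEMs) and tide-gauge datum tables, together
with a per-pixel standard deviation obtained by first-order error
propagation:

```
σ²_Z* = (∂Z*/∂Z)² σ²_Z + (∂Z*/∂MHW)² σ²_MHW + (∂Z*/∂MSL)² σ²_MSL
      + 2 (∂Z*/∂MHW)(∂Z*/∂MSL) σ_MHW σ_MSL ρ₂
```

where σ_Z combines LiDAR random error and the site-level uncertainty of
the vegetation bias correction in quadrature, the datum uncertainties mix
gauge-report error (spread by inverse distance weighting) with
interpolation error (ordinary kriging standard error), and ρ₂ is the
correlation between the MSL and MHW errors, which share gauges.  Marsh
below the MHW line floods roughly twice a day (low-elevation marsh); the
package converts Z* and σ_Z* into a probabilistic low/high-marsh map via
the standard normal CDF, estimates class areas with a binomial
probability-class estimator, summarizes watersheds, and models geographic
trends of median Z*, Z* variability and Z* uncertainty against tidal
amplitude and relative sea-level rise (AICc model selection, ω² effect
sizes, and a leave-one-out kriging model of the spatial residuals).

It is intended for coastal wetland scientists and geospatial analysts who
want a transparent, tested reimplementation of this mapping workflow that
can be exercised end-to-end without any external downloads: a bundled
synthetic-scene generator produces a coastal world (true surface, biased
and noisy elevation tiles, hydro-flattened water, a correlated-error gauge
network, land cover, watershed polygons, tide series) with known truth for
validation.

## Worked example

```python
from marshelev import ErrorBudget, compute_zstar, propagate_zstar_sigma
from scipy.stats import norm

budget = ErrorBudget()          # random 0.205 m, bias SE 0.110 m, rho2 0.873
print(budget.sigma_z)           # 0.233  (total elevation error, m)

z, msl, mhw = 0.62, 0.11, 0.83  # metres NAVD88
zstar = compute_zstar(z, msl, mhw)
sigma = propagate_zstar_sigma(z, msl, mhw, budget.sigma_z, 0.02, 0.03,
                              rho2=budget.rho2)
print(round(zstar, 3), round(sigma, 3))      # 0.708 0.325
print(round(norm.cdf((1 - zstar) / sigma), 2))  # 0.82
```

The pixel sits at Z* = 0.708 — about 71% of the way from mean sea level to
mean high water — but with a 0.72 m tidal amplitude the 0.233 m elevation
error alone makes σ_Z* = 0.325, so the pixel is low-elevation marsh with
probability 0.82 rather than with certainty.

The same computation over a whole synthetic coastal scene:

```python
from marshelev import PipelineConfig, SceneConfig, run_pipeline

config = PipelineConfig(scene=SceneConfig(seed=42))
run = run_pipeline(config, "demo_run")
```

which writes the DEM, datum fields, Z* and σ_Z* maps, probability maps,
area tables, watershed summaries and trend models into `demo_run/`.  For
this seed the estuarine-emergent class splits into 694.6 ± 2.0 ha of
low-elevation and 156.1 ± 2.0 ha of high-elevation marsh (82% low), and
watershed-level log σ_Z* regressed on log tidal amplitude has slope −0.96
(adjusted R² = 0.98), close to the analytic −1 expected when elevation
error dominates the budget.

The same stages are available from a shell:

```
marshelev run-all --seed 42 --out demo_run
marshelev simulate / prep-dem / interp-datums / zstar / classify / summarize / trends
```

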