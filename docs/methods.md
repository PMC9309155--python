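# Methods

## The quantity being mapped

`marshelev` maps relative tidal elevation, Z*_MHW = (Z − MSL)/(MHW − MSL),
with Z an orthometric ground elevation (metres NAVD88) and MSL/MHW the
local mean sea level and mean high water datums on the same vertical
reference.  Z* = 0 is the MSL line and Z* = 1 the MHW line; marsh below
MHW floods on roughly every high tide, marsh above it once daily or less
in mixed and semidiurnal regimes.  The package's contribution is not the
index itself but the transparent pixel-level uncertainty budget around it
and the probabilistic products built from that budget.

## Error model and propagation

Elevation error has two components, combined in quadrature
(σ_Z² = σ_random² + σ_bias²):

| parameter | default | units | meaning |
|---|---|---|---|
| `sigma_random` | 0.205 | m | per-pixel LiDAR random error in vegetated marsh |
| `sigma_bias`   | 0.110 | m | site-level SE of the single national vegetation bias correction |
| bias offset    | 0.173 | m | mean LiDAR overestimate subtracted from every DEM pixel |
| `rho2`         | 0.873 | – | correlation of MSL and MHW errors (shared gauges) |
| `rho`          | 0.716 | – | correlation of chained datum-transformation errors |

The defaults give σ_Z = 0.233 m and are treated as given constants of the
error model, applied as a spatial constant (a per-pixel override is
accepted for sensitivity runs).

Datum surfaces are interpolated from the gauge network by ordinary
kriging with a variogram fitted by weighted least squares; gauge-report
standard errors are spread by inverse distance weighting (power 2,
configurable); the two are combined in quadrature because datum error is
driven by record completeness and kriging error by distance from gauges.
Where a datum rides on a chained transformation (MHHWS on top of MHHW),
the two SE layers combine as σ_c = sqrt(σ_a² + σ_b² + 2ρσ_aσ_b).

σ_Z* follows from a first-order Taylor expansion with
∂Z*/∂Z = 1/A, ∂Z*/∂MHW = −(Z−MSL)/A², ∂Z*/∂MSL = (Z−MHW)/A² (A = MHW−MSL)
and a covariance cross term in ρ₂.  Because correlated MSL/MHW errors
move both datums together, the cross term is positive for elevations
inside the tidal frame and inflates the variance; this sign structure is
confirmed against Monte-Carlo sampling in the test suite.  A variant of
the MHW partial without the minus sign circulates in applied work; the
flag `as_printed=True` reproduces it (squared terms are unchanged, only
the cross term flips).  First-order propagation is accurate to a few
percent only while the datum errors are small against the amplitude: with
a datum SE at exactly A/5 the propagated SD can deviate from the sampled
SD by ~12% (the ratio distribution grows heavy tails), while at
gauge-report-realistic centimetre SEs the worst deviation observed over
hundreds of probed configurations is under 2%.  Validation draws
configurations in that realistic regime.

## Classification and area

Z′ = (x − Z*)/σ_Z* measures the distance to a threshold x (default 1, the
MHW line) in local error units; Φ(Z′) is the probability of lying below
it.  Probability maps are stored at two-decimal precision, and the
complement map is computed from the rounded values so the two classes sum
to exactly 1 per pixel.  Area treats each stored probability class
φ_i = i/100 (i = 0…100) as a binomial: mean = Σ n_i φ_i · a and
variance = Σ n_i φ_i(1−φ_i) · a² with a the pixel area (0.09 ha at 30 m).
Grouping by the rounded two-decimal value makes the class representative
exact rather than a bin-midpoint approximation; an unbinned estimator
over the unrounded probabilities is provided as the oracle and agrees
with the class-based one to within half a probability step per pixel.
The binary map uses the 50% boundary with ties assigned to the low class.

The same machinery produces the probabilistic below-MHHWS layer behind
the area-of-interest rule: estuarine emergent wetland is always analyzed;
palustrine, developed and upland classes only where P(below MHHWS) > 1%;
open water never.

## Watershed summaries and trend models

Zonal statistics (mean, SD, median, 2.5/25/75/97.5% quantiles, min, max,
plus medians of σ_Z*, tidal amplitude and RSLR) are taken over
estuarine-emergent AOI pixels whose cell centers fall in each polygon;
quantiles use linear interpolation between order statistics, cells claimed
by several polygons go to the lowest watershed id.  Watersheds with median
Z* above Q75 + 1.5·IQR of the medians are flagged and excluded from the
models (an explicit include-list can retain chosen ones); they stay in
listings.

Candidate covariate models are every submodel of {log amplitude, RSLR,
interaction} respecting marginality, ranked by AICc with
k = coefficients + 1 (the residual variance counts as a parameter, the
convention of the common model-selection tooling); ω² per term comes from
sequential (type-I) ANOVA.  Amplitude, IQR and σ_Z* are natural-log
transformed.  Z* uncertainty is modelled by simple regression on log
amplitude only; with a constant elevation budget the analytic slope is −1
exactly, and on default synthetic scenes the fitted slope lands around
−0.9 to −1.0 because kriging SE adds a weakly amplitude-dependent term.
Residuals of the selected model get a spatial model: per left-out
watershed the variogram is refitted to the others and ordinary kriging
predicts the held-out centroid; pseudo-R² = 1 − Σ(x_i−y_i)²/Σ(x_i−ȳ_i)²
with ȳ_i the calibration-fold mean, reported as 0 when all residuals are
equal.  The spatially explained share of total variance is
(1 − adj R² of the covariate model) × pseudo-R².

RSLR is the OLS slope of monthly mean water level (mm) on fractional
year; gauges with under 66% of the window's months are excluded.  Tidal
metrics recomputed from water-level series use local-maximum detection
with a 10-hour minimum separation (a documented stand-in for a published
supplementary procedure): MHW is the mean of all highs, MHHW of daily
highest highs, and MHHWS is interpreted as the mean of monthly maximum
highs; HOT is the observed maximum and HAT the maximum of the noise-free
constituent reconstruction when available.  Starred metrics normalize by
the tidal frame ((HAT−MSL)/A, DHQ/A).

## The synthetic scene

The generator emulates the statistical structure the analysis assumes,
not coastal geomorphology: a smooth true surface whose relative elevation
ramps from subtidal to upland with smooth bumps; a tidal amplitude that
increases linearly south to north (0.6–2.4 m by default); observed tiles
= truth + one site-bias draw per tile (N(0.173, 0.110²)) + iid pixel noise
(N(0, 0.205²)), with open water hydro-flattened to a sentinel; gauge MSL
and MHW errors drawn jointly with correlation 0.873; latitudinal
watershed bands; M2+K1 tide series (mixed regime, nonzero diurnal
inequality) and monthly mean-level records carrying a north–south RSLR
gradient.  One master seed spawns independent child streams per
component, so identical configurations are bit-for-bit reproducible.

Default sizes are chosen to reproduce the analysis regime rather than any
particular map: 64 gauges on the 120×160-cell default grid keep datum
interpolation error subordinate to elevation error for ~80% of pixels
(the regime the error model assumes, where elevation error dominates),
and 24 watershed bands give the trend models a usable sample.  An
optional correlated-noise switch (`noise_correlation_range`) replaces the
iid pixel noise with a smoothed field.

What the generator does *not* emulate: realistic shorelines, tidal
damping over marshes, spatially autocorrelated LiDAR error by default,
water-control structures, or the multi-decadal datum epochs of real
gauges.  Passing tests therefore demonstrate the correctness of the
computational chain under its stated assumptions; they do not certify
accuracy over real terrain, where bias varies by vegetation community and
errors are spatially structured.

## Numerical choices

- Grid registration: cell centers, upper-left origin, row-major; rasters
  exchanged as ESRI ASCII grids (text).
- Resampling: equal-weight mean of native cells per 30 m cell; nodata only
  when all contributors are nodata; masked water never enters a mean.
- Mosaicking: newest survey date wins; nodata falls through; date ties
  break lexicographically on tile id.
- Variogram fitting: ~10 equal-width bins to half the maximum pairwise
  distance, WLS with pair-count weights, exponential family by default;
  degenerate inputs fall back to a near-flat variogram so the kriging
  system stays solvable.  γ(0) = 0 exactly, making ordinary kriging an
  exact interpolator with zero SE at gauges even with a nugget.
- Nodata always propagates; no zero-filling anywhere in the chain.
- Manifests contain no timestamps, so reruns are byte-identical.

## Validation design and limitations

Two subtleties shape the calibration check of the probability maps.
First, the binomial comparison of per-bin truth fractions against the
stored probabilities is exact only when the prior density of true
relative elevation is locally flat and pixel errors are independent; real
terrain bends the conditional probabilities by a few percent, and near
the shoreline the prior is hard-truncated (subtidal cells are
hydro-flattened away), which can push individual bins several points off
nominal no matter how well the classifier works.  The strict
exact-binomial assertion therefore runs on a field with a uniform
relative-elevation prior and iid budget-level noise, where the guarantee
holds; the full-scene path is additionally required to be structurally
calibrated (monotone, within 15 points).  Second, the error budget
describes the DEM at the analysis scale: noise injected at finer native
resolution is attenuated by the block-mean resampling (a 3×3 mean cuts an
iid σ by 3), so calibration scenes inject the budget at 30 m.  Both
points carry over to real data: aggregation shrinks random error while
the bias and datum components, being spatially structured, do not cancel.

Problem sizes throughout (120×160 to 200×200 grids, 10⁶-draw Monte-Carlo
oracles, 50-replicate recovery studies) were chosen so the entire
validation suite runs in well under an hour on one core while leaving the
statistical assertions well-powered.

Known limitations: no spatial autocorrelation is modelled when
aggregating pixel uncertainties to areas or watershed statistics
(variances over regions are therefore approximate); empirical Bayesian
kriging of the original workflow is replaced by ordinary kriging with a
fitted variogram (the interpolation contract — exactness at gauges plus a
prediction SE surface — is preserved, the simulation-based intensity
estimation is not); no hydrodynamic constraints on datum surfaces; no
reprojection beyond same-CRS alignment.
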