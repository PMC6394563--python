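# Methods

`pcamars` interpolates an urban air-pollutant concentration field (the
package is written around NO₂ in µg/m³) from a sparse monitoring network by
regressing station values on principal components of a GIS-engineered
covariate stack with multivariate adaptive regression splines (MARS), and
compares the result against the classical spatial interpolators (IDW,
ordinary kriging, MARS on coordinates-plus-elevation only).

## Pipeline

All analysis happens on one north-up grid of square cells (default 500 m,
60 × 80 cells ≈ a 30 km × 40 km city). Three stages:

**1 — Covariate engineering** (`features`). Fourteen covariate rasters in a
fixed order: four meteorological surfaces (wind speed, temperature,
pressure, relative humidity) interpolated from point samples by IDW with a
power chosen per variable by leave-one-out RMSE over {1, 2, 3}; four POI
density surfaces (gas facilities, petrol facilities, green areas, sport
fields), population density and road density by planar kernel density
estimation with the quartic kernel K(u) = (3/π)(1 − u²)² (lines are
densified every half cell and weighted by represented length; population
polygons contribute their centroid weighted by population); elevation
(resampled DEM) and focal-mean "average elevation"; and the two cell-centre
coordinate rasters. Every focal/KDE neighbourhood radius is selected by
sweeping a candidate grid (default 1 cell up to 25 % of the shorter grid
extent, 1-cell steps) and keeping the radius maximizing |I|, the magnitude
of the bivariate Moran's I between the station values of the dependent
variable and the candidate surface sampled at the stations:

    I = (n / S₀) · Σᵢⱼ wᵢⱼ ẑᵢ ĉⱼ / √(Σ ẑ² · Σ ĉ²)

with mean-centred variables and an inverse-distance (power 1,
zero-diagonal) station weight matrix held fixed across candidates. |I|
rather than signed I because green-space covariates are expected to
correlate negatively with the pollutant. All layers are min–max normalized
to [0, 1] with the bounds retained for prediction.

**2 — Dimension reduction** (`pca`). PCA by eigen-decomposition of the
sample covariance of the 14 normalized layers over *all valid pixels*
(21 station rows cannot stably estimate a 14 × 14 covariance); the first
k = 3 components are kept by default. Covariance, not correlation, since
the inputs share the [0, 1] scale. Eigenvector signs are fixed
(largest-magnitude element positive) so runs are bit-reproducible.

**3 — Regression** (`mars`). Piecewise-linear MARS:
f(x) = c₀ + Σ cᵢ Bᵢ(x), each Bᵢ a product of hinges max(0, ±(x_v − t)).
The forward pass greedily adds reflected hinge pairs — every existing basis
function of degree < 2 as parent, every variable it lacks, every eligible
observed value as knot — committing the pair with the largest SSE decrease
(coefficients refitted by least squares each time; candidate scoring uses a
vectorized 2×2 Schur complement, the committed model a full refit). The
backward pass deletes one basis function at a time (always the one whose
removal raises SSE least) and returns the member of the nested sequence
with the lowest generalized cross-validation score

    GCV = (SSE/n) / (1 − (m + d(m−1)/2)/n)²,

m counting the intercept and d defaulting to 3. The fitted model is
evaluated at every pixel's PC scores to produce the concentration map.

## Numerical and design choices

* **Knot eligibility (endspan).** A candidate knot must have at least
  ⌈3 − log₂(0.05/p)⌉ parent-support observations strictly on each side
  (capped so interior knots always remain). Without this rule, hinges
  fitted on one or two edge points acquire coefficients in the hundreds and
  extrapolate to physically impossible concentrations at held-out
  locations. No minspan (interior thinning) is applied: interior knots at
  adjacent data values are what lets a noiseless hinge be interpolated
  exactly.
* **Rank guarding.** A hinge column numerically inside the span of the
  current design (reflected pairs on one variable overlap linearly) is
  dropped at commit, so coefficients always solve well-posed normal
  equations.
* **No extrapolation beyond the design hull.** At prediction time PC
  scores (and the MARS3 design) are clamped per column to the training
  range: hinge models are linear beyond the last knot, and 21 stations
  leave the pixel-score extremes unsupported. The clamp is a config switch
  (`clip_scores`).
* **Degenerate inputs.** Constant layers fail min–max normalization
  explicitly; zero-variance variables make Moran's I undefined and raise;
  degenerate covariates score NaN in the radius sweep and cannot win;
  effective parameters ≥ n makes GCV infinite.
* **Ties.** Equal SSE gains resolve to the earlier parent, smaller
  variable index, then smaller knot; equal LOOCV RMSE resolves to the
  smaller IDW power (with a 1e−9 relative tolerance so floating-point noise
  does not break ties); equal GCV keeps the larger (earlier) model.
* **Cell containment** is half-open (a point on a shared edge belongs to
  the cell right/below); row 0 is the northernmost row. Focal
  neighbourhoods use strictly-less-than the radius, so a one-cell radius is
  a singleton neighbourhood.
* **Per-fold refitting in LOOCV.** Everything that consumes station NO₂ —
  the Moran radius sweep, the PCA on the resulting per-fold stack, the MARS
  stage — is refit on each fold's n−1 stations; candidate focal/KDE
  surfaces depend only on the radius and are cached across folds.
  `freeze_radii` selects radii once from all stations (the simpler, mildly
  leaky protocol) and then also fits PCA once.
* **IDW power on a trend.** Under leave-one-out RMSE a pure linear field
  selects the *largest* candidate power (localization beats the global
  averaging of power 1); the selector simply returns the LOOCV argmin and
  asserts nothing else.
* **Variogram fitting** is count-weighted least squares over (nugget,
  partial sill, range) with non-negativity bounds; on optimizer failure a
  pure-variance fallback (nugget 0, sill = mean semivariance, range = half
  the maximum lag) is used with a warning.

## The synthetic scene

`scene.generate_scene` builds complete reproducible test cities. A latent
multi-centre *urban-intensity* field (a primary downtown plus ~4 weaker
sub-centres, widths 8–18 % of the city span) governs where roads, POIs and
population blocks concentrate, reproducing the co-location of traffic and
human-activity covariates that real cities exhibit — and that makes a
leading "urban intensity" principal component meaningful. Green areas and
sport fields are placed preferentially *away* from the dense core. The DEM
ramps from ≈1700 m in the north to ≈1100 m in the south plus smooth bumps,
like a foothill city; meteorological fields follow the DEM (lapse-rate
temperature, pressure) plus smooth noise.

The ground-truth concentration surface is

    truth = base (60 µg/m³)
          + Σ βᵢ · gᵢ(normalized covariate smoothed at its acting radius)
          + spatially correlated residual (SD 3 µg/m³, 3 km correlation length)

with hinge responses g(s) = max(0, s − 0.3)/0.7 for roads and population
(no effect until density clears a floor — and hinge nonlinearities put the
truth inside MARS's function class, so knot recovery is a meaningful test,
not a coincidence) and linear responses otherwise. Default effect sizes
(roads +35, population +28, gas +18, petrol +15, green −22, sport −10,
average elevation +30, temperature −8, wind −8 µg/m³ across each
covariate's range) and acting radii (2–3 km) were chosen once so the scene
reproduces the magnitudes the study reports: station-to-station differences
of tens of µg/m³, leave-one-out RMSEs of roughly 10–25 µg/m³ for all
methods, elevated concentrations on the high northern side, and a citywide
trend strong enough that a coordinates-plus-elevation regression is a
serious baseline. Stations (default 21) are a jittered grid; measurements
add white noise of SD 5 µg/m³.

What the generator does **not** emulate: temporal structure (each scene is
one snapshot), anisotropic dispersion and wind-driven advection, real
street-network topology, terrain-blocked neighbourhood effects, and
station-siting bias toward hotspots. Passing tests therefore demonstrate
correctness and the qualitative method ordering *under the generator's
assumptions*, not performance on any real monitoring network.

## Problem sizes

Tests and the comparison harness run the default 60 × 80 grid with 21
stations; the method-ordering check uses 20 scene seeds, the planted-effect
recovery check a denser 60-station network, and MARS engine checks samples
of 50–200 points — sizes at which every property is estimated stably while
a full test run stays inexpensive.

## Known limitations

* With ~21 stations spaced wider than the candidate radii, the
  zero-diagonal Moran sweep carries little information about small radii
  and drifts toward smooth surfaces; the planted-radius recovery test uses
  a denser network where the statistic is informative. This mirrors a real
  limitation of the method, not an implementation defect.
* Kriging uses a single isotropic spherical model; no anisotropy, no
  universal/co-kriging.
* The thin-plate-spline and co-kriging baselines of the original comparison
  are not implemented; `compare_methods` accepts externally computed
  fold predictions so they can be slotted in.
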