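# Methods

## Raster model and conventions

All layers live on axis-aligned grids in a single projected equal-area
coordinate system: top-left origin, row-major storage, pixel area
`cell_size²`. Densities per km² are therefore plain cell-count
arithmetic, which matches how the per-level population densities are
defined. Missing data is an explicit boolean mask; masked cells are
excluded from every statistic and fit, and no operation writes values
into them. Two grids are *aligned* iff they share shape, cell size and
origin.

Nearest-neighbour resampling assigns each output pixel the value of
the source pixel whose centre is closest to the output pixel centre;
exact ties (an output centre on a source-pixel boundary) go to the
top-left candidate so results are deterministic. Resampling a coarse
grid to a finer one therefore block-replicates values, and refining
then coarsening back is the identity. When the extent is not an
integer multiple of the target cell size the output is padded with
nodata.

Temporal averaging over the May–September stack is the per-pixel
arithmetic mean of the valid months; a pixel is masked when fewer than
`min_valid_months` (default 1) months are valid. The multi-year record
enters as one flat list of monthly composites — compositing 8-day and
16-day products to months is upstream of this package and is emulated
directly by the scene generator.

I/O: single-band GeoTIFF (float32 continuous / int16 categorical, with
pixel-scale, tiepoint and nodata tags written and read directly) and a
plain-text grid dialect (`ncols/nrows/xllcorner/yllcorner/cellsize/
nodata_value` header then rows) for human-readable fixtures.
Categorical rasters carry their label table in a `.labels.csv` sidecar
so round-trips preserve it.

## Hazard: per-class downscaling of LST by NDVI

Coarse (1-km) monthly LST is paired with 250-m NDVI by resampling the
LST and the land-cover grid to the NDVI grid; every valid 250-m cell
contributes one (NDVI, LST, class) triple per month, with water cells
(land-cover code 210) excluded throughout. One model per land-cover
class and period is fitted, pooling all months — a single predictive
model per class keeps the procedure robust to the within-class
emissivity variability that plagues urban thermal retrievals. Classes
with fewer than 30 pairs, or with degenerate NDVI, inherit the model
pooled over all classes (the threshold is the usual small-sample rule
of thumb; the analysis is insensitive to it because default scenes
give thousands of pairs per class).

**Linear model.** OLS of LST on NDVI via statsmodels; reported metrics
are in-sample R², the slope with its two-sided p-value, and RMSE.
Because each coarse LST value is replicated across the ~16 fine cells
of its block, OLS residuals cluster by block and the naive slope
standard error is anti-conservative; the reported `slope_se` is
therefore cluster-robust by coarse block, and slope-recovery checks
use it.

**Additive smooth model.** A univariate penalized regression spline in
the Eilers–Marx P-spline form: cubic B-splines on equally spaced knots
(10 interior, extended beyond the data range), second-order difference
penalty on the coefficients, smoothing parameter λ selected by
generalized cross-validation, GCV(λ) = n·RSS/(n − edf)², on 25
log-spaced points in 10⁻⁴…10⁴, with edf the trace of the smoother
matrix. Equally spaced knots (rather than NDVI quantiles) are a
deliberate choice: they make {constant, linear} exactly the null space
of the penalty, so the linear model is nested in the smooth at every
λ and in-sample RMSE(GAM) ≤ RMSE(LRM) holds structurally — a property
the tests assert at tolerance 1e-8 and that quantile knots would not
guarantee. Significance is an approximate F-test of the smooth against
the intercept-only model with edf − 1 numerator degrees of freedom.
Predictions outside the fitted NDVI range are clamped to the range
endpoints (constant extrapolation). On one synthetic class the fit
agrees with R `mgcv`'s default thin-plate smooth to within a few
tenths of a percent of RMSE, which the test suite checks.

Fine LST is predicted per pixel by its class model, monthly; the
summer mean of the predictions, resampled to 100 m, is the hazard
layer. The fit report tabulates per-class metrics with an averages row
per period and model family; the averages row is the unweighted mean
across classes by default, with an `n_obs`-weighted variant available
because the published per-class tables do not state their weighting.

## Exposure and vulnerability

Exposure is the 100-m total-population grid (persons per cell),
mask-harmonised to the analysis (water) mask. Vulnerability multiplies
each pixel's total population by the elderly fraction of the pixel's
municipality, so municipal elderly sums reproduce the administrative
totals exactly; elderly counts stay real-valued (a percentage applied
to a density surface) and 0 ≤ elderly ≤ total holds per pixel.
Missing fractions raise an error naming the municipality code.

## Risk index

Each of the three layers is normalized per city and per period.
Min–max, `(x − min)/(max − min)`, is the default: the stated goal of a
common 0-to-1 scale is only guaranteed by min–max, while the literal
divide-by-range variant is kept behind a config switch. Constant
layers are rejected (no risk gradient is expressible). Zero-population
pixels are retained — zero exposure is a valid riskless state and such
pixels normalize to the layer minimum rather than dropping out.

The combination is `HERI = 0.5·H + 0.5·(0.5·E + 0.5·V)`, a convex
combination, monotone in each input and equal to L when all three
layers equal L. Classification into the five levels puts boundary
values in the lower level (x ≤ 0.2 is very low, 0.8 < x is very high);
a 1e-12 epsilon guards float jitter exactly at the cuts, and values
outside [0, 1] beyond 1e-9 are rejected.

Zonal summaries per level report mean/SD of LST (population SD, so a
single-pixel level has SD 0), coverage as a share of unmasked land
pixels, population frequency as a share of city totals, and density
as level population over level area; empty levels report zeros.
Cross-city aggregation is the unweighted mean of coverage percentages
across all (city × period) members of a group.

## The synthetic scenes

A scene is a 30 km × 30 km city on the 100-m grid (multiples of 3 km
are required so the 250-m, 300-m and 1-km layers tile the same
extent). Its components:

- **Land cover** (300 m): concentric square rings from a built-up core
  (C190) outward through progressively greener classes; ring
  boundaries sit on the 3-km grid so every 1-km LST cell is pure in
  class, and the coastal preset floods an exactly 3-km stripe (water,
  C210) on the east edge. A "blobs" Voronoi layout exists for
  irregular geographies.
- **NDVI** (250 m, monthly): class mean + kilometre-scale structure
  (a radial greening gradient away from the core and a Normal(0, 0.06)
  per-1-km-block texture, both constant within each block) + a global
  seasonal cosine (amplitude 0.03, peak early summer) + a faint
  Normal(0, 0.005) cell ripple, clipped to [−0.1, 0.9]. Keeping the
  informative NDVI variation block-constant at 1 km means the coarse
  block means remain an exact function of fine NDVI within each class,
  so regression recovery is attenuation-free by construction; the cell
  ripple adds realistic texture without breaking it.
- **Truth LST** (100 m): per class a monotone *decreasing* response to
  NDVI — linear (`a + b·NDVI`, intercepts ~30–35 °C, slopes −3.5 to
  −16 °C per NDVI unit, spanning the published daytime range) or
  saturating (`top − drop·tanh(NDVI/scale)`), the latter providing the
  nonlinearity the smooth model should exploit. Night truth is day
  truth minus a 13 °C urban day/night offset.
- **Coarse LST** (1 km, monthly): the 10×10 block mean of the truth
  over valid cells plus i.i.d. Gaussian noise — 1.0 °C by day, 0.4 °C
  by night. The ratio mirrors the roughly halved night-time fit RMSE
  in the published tables (night-time retrievals are less variable
  because sunlight/shadow heterogeneity is absent).
- **Population** (100 m): an exponential surface, e-folding 2 km
  (2.5 km coastal) from the centre, zero on water, rounded to whole
  persons by largest remainder so the 350,000-person city total is
  conserved exactly. **Municipalities** are a 5-seed Voronoi partition
  with elderly fractions 0.18–0.24, bracketing the ~21 % national 65+
  share.

Everything is deterministic given the spec seed. What the generator
does **not** emulate: real urban morphology, cloud/QA gaps, emissivity
bias, LST–air-temperature differences, spatially correlated retrieval
noise, or dasymetric error in the population grid. Passing tests
therefore demonstrate the correctness of the statistical machinery
under the stated generative assumptions, not the accuracy of any
particular real-city map.

## Numerical and design notes

- Spline systems are solved by Cholesky factorization of B'B + λD'D
  (14 basis functions); the GCV winner is kept.
- Slope-recovery tests compare against generator truth within 3
  cluster-robust standard errors; with ~150–1,000 coarse blocks per
  class this is an honest interval under the block-replicated design.
- Per-level population density is only *generally* increasing in risk
  level: isolated cold pixels inside the dense core can land in the
  very-low level with above-rural density, the same inversion the
  published per-city tables show. The regression test asserts strict
  monotonicity from the low level upward and the maximum at very high.
- Default problem sizes (30 km scenes, 72,000 training pairs, 90,000
  100-m pixels) were chosen so each full city analysis completes in
  under a second while keeping per-class samples in the thousands —
  the same order as the per-class metric tables the method was
  designed around.
- Known limitations: fits are in-sample (matching the descriptive use
  of the published metric tables); no held-out validation, no
  LST-to-air-temperature conversion, and no epidemiological
  calibration of the index weights (all weights deliberately equal).
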