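# Methods

This note documents the models and procedures `pixelyield` implements,
the choices made where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Data model and zonal statistics

Rasters are planar projected grids (metres), origin at the top-left
corner; cell (row, col) has its centre at (x₀ + (col+½)·res,
y₀ − (row+½)·res) and owns the half-open square [x, x+res) × (y−res, y].
The toolkit never reprojects: all inputs must share one CRS.  Zonal
aggregation uses pixel-centre inclusion — a pixel contributes to a
polygon iff its centre is covered by the polygon and it passes the crop
mask and is not nodata.  Villages with zero eligible pixels are flagged
(count 0, mean NaN), never silently zeroed.  Monthly composites average
repeat acquisitions per pixel, treating a pixel as nodata only when it
is missing in every acquisition.

Village samples are assembled per dataset combination (band, weather and
soil groups in seven named subsets).  Missing village yields are imputed
with their block mean *before* the train/validation split; villages in
blocks with no reported yield at all are dropped.  The split is a simple
seed-reproducible random partition with ⌊0.8·n⌋ training samples
(1,116 → 892 + 224); stratification is not used.

## Screening baselines

Linear, ridge and lasso regression and the RF/GB/XGB ensembles stand
behind scikit-learn/xgboost estimators with pinned hyperparameters
(100 trees; learning rate 0.1 for the boosted models; bootstrap for the
forest; seed 42); anything unpinned stays at library defaults.  Features
are z-scored on the training split for the regularized regressions (the
reported coefficients are mapped back to the original scale); plain
linear regression and the tree models use raw features.  Dataset
combinations are compared by validation RMSE with a Friedman test
(average ranks, mid-ranks for ties, no tie-correction term — the
classical χ²_F form) and the Nemenyi critical difference, whose q_α
constants (k = 2…20, α ∈ {0.05, 0.10}) are the studentized-range
quantiles at infinite degrees of freedom divided by √2; CD(7, 6, 0.05) =
3.6772.

## Recurrent downscaler

Architecture: band sequence (3×7) and weather sequence (5×6) each feed
their own recurrent cell with 32 units and a 16-unit ReLU dense layer;
the two 16-wide summaries are concatenated with the static input
(width 1, a crop indicator by default) into a 33-wide vector, then a
128–64–32 ReLU head with dropout 0.1 after each head layer, and a single
Softplus output enforcing ŷ ≥ 0.  The LSTM cell uses the standard
i/f/g/o gating (4·(d·h + h² + h) weights); the GRU uses the
reset-after, double-bias formulation (3·(d·h + h² + 2h)), which is what
makes the totals come out at 25,889 (LSTM) and 23,553 (GRU) — the
single-bias GRU count (23,361) is inconsistent with the reference total,
so the convention is pinned.

Both cells, backpropagation through time, Adam and the training loop are
implemented directly on numpy arrays.  This keeps training bit-exactly
deterministic under a seed with no framework-level determinism flags,
and the backward pass is verified against central finite differences in
the test suite.  Training: Adam (lr 10⁻³ unless overridden), MSE loss,
MAE monitored, batch 32, up to 500 epochs, early stopping on the
validation loss with patience 25 and best-weight restoration (the
monitor can be switched to validation MAE).  Inputs are z-scored per
feature with training-split statistics that are stored on the model and
re-applied at prediction time.  The output bias is initialized to the
inverse-Softplus of the mean training yield so the optimizer starts at
the right scale — without this, reaching a ~45 q/ha output level from
Softplus(0) would dominate the epoch budget.  Dropout placement (after
each head layer) and input scaling were open choices; both are recorded
in the model configuration.

Pixel inference flattens the covariate stack into per-pixel band/weather
sequences plus the static column, applies the stored standardization,
and writes NaN outside the crop mask.  Village means of the pixel raster
coincide with the zonal aggregation of that raster by construction.

## Residual kriging

Residuals e_i = y_i − ŷ_i are located at village centroids.  The
empirical semivariogram uses 15 equal-width lag bins up to half the
maximum pairwise distance (defaults; both configurable).  Variogram
models: linear γ = c₀ + b·h (unbounded, excluded from simulation);
spherical; Gaussian γ = c₀ + c(1 − e^{−(h/r)²}); exponential
γ = c₀ + c(1 − e^{−h/r}).  The range parameter is the e-folding scale,
not the 95% effective range.  Fitting is weighted least squares with
pair-count weights, initialized at nugget 0, sill = mean semivariance,
range = ⅓ of the largest lag; a non-converging nonlinear fit falls back
to the closed-form linear fit with a warning.

Model selection is leave-one-out cross-validation: each candidate is
fitted once to the full empirical semivariogram, every point is then
predicted by ordinary kriging from the remaining points, and the
candidate with the lowest CV-RMSE wins, ties broken in the fixed order
linear < spherical < gaussian < exponential.  LOO was chosen because it
is deterministic (no fold seed) and cheap at village counts.

Ordinary kriging solves the augmented system Γλ + μ1 = γ₀, 1ᵀλ = 1 with
one LU factorization shared across all prediction pixels (global
neighbourhood up to 1,000 points; beyond that, the 64 nearest points per
target).  Convention for the nugget: γ(0) = 0 on the data-data diagonal,
while prediction right-hand sides use the nugget as the h→0⁺ limit —
this yields exact interpolation when the nugget is zero and the usual
smoothing behaviour when it is positive.  The correction step is plain
addition y* = ŷ + e_krig with nodata propagation; clipping negative
corrected yields at zero is available but off by default.

The kriging-only benchmark ("area-to-point" surrogate) applies the same
ordinary-kriging engine to the village yields themselves at centroid
support; true area-to-point kriging with within-area covariance
integration is out of scope.  The NDVI weight-based allocator
(allocation_p = NDVI_p/ΣNDVI · P) conserves the unit's production
exactly and refuses units with non-positive NDVI sums; the percentile
allocator implements the pure-slope scaling
(Max−Min yield)/(NDVI₉₅−NDVI₅) · NDVI_p with no intercept term — common
variants add a minimum-yield offset, but the plain slope form is kept
deliberately, so zero NDVI maps to zero yield.  Both use the seasonal
mean NIR/Red composite (peak-value compositing is available via a flag
on the NDVI inputs).

## Evaluation statistics

R², adjusted R² (penalized by predictor count), RMSE, MAE and MAPE (in
percent, zero-valued observations excluded with an exclusion count)
follow their textbook forms.  Block-level reports omit R²: with a
handful of blocks the statistic is unstable.  Moran's I uses binary
k-nearest-neighbour weights (k = 8) symmetrized by max(W, Wᵀ), no row
standardization, and one-sided permutation inference with 999
permutations by default (p-value floor 1/1000); the expectation under
spatial randomness is −1/(n−1).

## Synthetic scenes

The generator emulates the study's data geometry on a 10 km × 10 km
grid (100×100 pixels at 100 m): pixel truth = intercept (45 q/ha)
+ 3·fertility + 2·moisture + 1·weather + bias, where fertility and
moisture are unit-variance exponential random fields with 1 km and
0.5 km ranges (field-scale variation), weather is a block-constant
standard-normal driver on 5 km blocks — at the reanalysis-to-scene
resolution ratio a weather cell covers many villages, so many villages
share identical weather values — and bias is a structured residual
field (default: exponential, partial sill 4 (q/ha)², range 3 km) that no
covariate carries.  Band layers are seasonally weighted mixes of the
drivers plus independent noise on positive reflectance-like baselines
(NIR above Red, so NDVI is positive); weather layers are deterministic
mixes of two latent block drivers (reanalysis features are strongly
cross-correlated — giving each layer independent block noise would hand
the models dozens of free spatial degrees of freedom that real weather
does not provide); soil layers are static fields partially correlated
with fertility.  The crop mask thresholds a smooth random field at the
configured coverage (default 0.7), giving patchy, spatially coherent
cultivation.  Villages are Voronoi cells of uniform random seeds,
rasterized by nearest-seed labelling and polygonized as exact pixel-cell
unions, so polygon membership and the label raster agree exactly;
blocks are the quadrant grouping of village seeds.  Observed village
yields are masked means of the truth plus N(0, 1 q/ha) observation
noise — the magnitude of crop-cutting-experiment error at village
aggregation.

Random fields are simulated by circulant embedding on a torus padded to
at least eight correlation lengths (negative embedding eigenvalues,
which are then negligible, are clipped), with nugget noise added
independently.

The default scene parameters were chosen once to mirror the study's
conditions at desk scale — the bias magnitude (sd 2 q/ha at pixel
support) corresponds to the 3–8 q/ha village residual errors reported
for the real models, scaled to the smaller yield variance of a
single-district-sized scene — and are not tuned per experiment.

## The bias-injection experiment

The end-to-end check of the hybridization trains the downscaler on a
scene, then injects an *independent* smooth regional bias — a
Gaussian-variogram field with the scene's sill and range — into the
truth and the observed village yields, and asks whether (a) the
pre-kriging village residuals are significantly spatially clustered
(Moran permutation p ≤ 0.01) and (b) residual kriging cuts the
village-aggregated RMSE by at least 20%.  Injection after training is
deliberate: with ~48 training villages a 23k-parameter network absorbs
most of any bias present during training through the smooth covariates
(an in-sample effect that the real study, with 892 training villages,
suffers far less), which would make the experiment measure memorization
rather than the correction.  Injecting afterwards creates exactly the
situation residual kriging exists for — a regional effect the fitted
model cannot express — under controlled conditions.  A Gaussian
(smooth) variogram is used for the injected field because the scenario
being emulated is a smooth regional bias; rough exponential draws
sometimes carry little village-scale autocorrelation on a small domain.

## What the synthetic experiments show — and don't

Passing tests demonstrate that the implementation is internally correct
(oracles, closed forms, conservation and exactness identities) and that
the hybrid workflow recovers injected regional structure under the
generator's assumptions: Gaussian fields, linear covariate links plus
noise, exact Voronoi administration, stationary isotropic residuals.
Real landscapes violate all of these — phenology is nonlinear, yields
are not Gaussian, administrative units are not Voronoi cells, weather
bias is not stationary — so the synthetic results validate the
machinery, not the agronomic claims.

## Numerical choices and degenerate inputs

- Kriging weight sums are audited; the worst |Σλ − 1| is reported in the
  run manifest (observed ≲ 10⁻¹⁰).
- Duplicate point locations raise a linear-algebra error rather than
  being jittered silently.
- A constant residual field is rejected by Moran's I (undefined) and
  fits a pure-nugget variogram.
- A NaN training loss aborts with a diagnostic rather than continuing.
- MAPE excludes zero observations with a count, rather than failing.
- Problem sizes in the test suite (scenes of 30–100 px per side, 8–60
  villages, 10–20 seed replicates) were chosen as the smallest at which
  each statistical property is comfortably detectable.

## Known limitations

Centroid-support kriging stands in for true area-to-point deconvolution;
kriging variance (uncertainty) maps are not produced; universal kriging
/ external drift, co-kriging, and attention-based temporal models are
out of scope.  Residuals are not detrended before kriging.  The CLI
reads whole scenes into memory; grids far beyond ~10⁶ pixels would need
tiling.
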