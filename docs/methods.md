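# Methods

## Model and estimator

`fracland` treats cropland allocation as a fractional response problem with
a support mismatch: the outcome (land shares `y_jk` over K categories,
category 1 the base "all other uses") is observed per administrative unit
`j`, while the covariates `X_ij` vary per pixel `i` inside the unit. The
conditional mean of the unobserved pixel share is a multinomial logit
`G_ijk = softmax_k(W_ij β_k)` with `β_1 ≡ 0`; area-weighted aggregation
`H_jk = Σ_i G_ijk A_ij / Σ_i A_ij` maps it to the unit level, and the free
parameters maximise the multinomial quasi-log-likelihood
`L = Σ_j Σ_k y_jk ln H_jk`. With exactly one pixel per unit and K = 2 this
collapses to the standard fractional logit of the quasi-binomial family,
and the test suite verifies that the likelihood, score and estimates then
coincide with a directly coded fractional logit and with an independent
GLM fit.

The QMLE is consistent under correct specification of the conditional mean
alone; no distributional claim is made about `y` given `H`. The estimator's
assumptions, in order of importance: (i) the mean is a softmax in the
chosen design; (ii) units are independent sampling blocks; (iii) every unit
has at least one non-excluded pixel; (iv) pixel areas are positive and
exogenous.

### Optimisation

BFGS ascent on `L` from `β = 0` (the uniform-shares model — a neutral,
always-feasible start), using the analytic score assembled through
`∂G_ijk/∂β_{k'm} = G_ijk (1{k=k'} − G_ik') W_ijm`. Convergence requires
gradient max-norm below `tol` (default 1e-6); a non-converged fit is
returned flagged with a warning, never silently. The likelihood refuses
evaluation once any |β| passes 1e3 and raises a separation error, so an
optimiser diverging under quasi-complete separation fails loudly. Softmax
uses the usual log-sum-exp shift, stable to |linear predictor| ≈ 700;
`0 · ln(·) = 0` by convention in the likelihood. Parameters are stored flat
in crop-major order (all M coefficients of category 2, then category 3, …);
every covariance matrix indexes the same way, and the serialized fit
records this convention.

### Uncertainty

The sandwich covariance is `F⁻¹ B F⁻¹ / J`, where `F` is the negated
average per-unit Hessian at the maximiser and `B` the average outer product
of the per-unit scores `s_j = ∂(Σ_k y_jk ln H_jk)/∂β`. The per-unit
averaging convention (rather than sums) follows the standard fractional
logit literature and makes the `/J` factor explicit; it is recorded in the
serialized output. `F` is obtained by central finite differences of the
analytic score with step `1e-5·max(1, |β_i|)` per coordinate — accurate to
roughly square-root machine precision, which is ample since `F` enters only
the variance, not the estimate. A condition number of `F` above 1e10 raises
an error pointing at collinear design columns. The block bootstrap
resamples the J units with replacement and carries *all* pixels of each
sampled unit (preserving the pixel-to-unit ratio), refits from the
full-sample estimate, and takes the covariance of replicate estimates;
replicates that fail to converge are dropped with a warning, and more than
20% dropped is an error. Fewer than 2 replicates cannot form a covariance
(error); fewer than 50 is allowed but warned about as noisy.

On correctly specified synthetic data the two covariance estimates agree to
within a few percent on standard errors; off-diagonal entries are compared
on the correlation scale, because a bootstrap correlation at B = 200
carries Monte-Carlo noise of about `1/√200 ≈ 0.07` regardless of the
estimator's quality, making raw relative error on near-zero covariances
uninformative.

## Design matrix

Transformations supported: linear, square, pairwise interaction, hinge
pair `max(pivot − x, 0)` / `max(x − pivot, 0)` (asymmetric response around
an optimum, e.g. soil pH 6.5), and group indicators (one column per
non-base level, first sorted level as base, identical across crops).
Column order follows the term list exactly, intercept first. Marginal
effects chain-rule through every term containing a variable; at a hinge
kink the derivative is taken as 0 from both hinge terms (a subgradient
choice). Reported effect tables list hinge terms as their own rows (the
transformed value treated as the regressor, so the odds ratio is exactly
`exp(β)`), continuous variables as chain-rule derivatives, and indicator
levels as discrete changes `G(level) − G(base)`. Averages over pixels are
unweighted by default, with area weighting as an option.

## Geometry

Pixels are cells of the global graticule, identified by their centre,
half-open `[lo, hi)` so boundary membership is unambiguous. Areas use a
spherical Earth of radius 6371.0 km:
`A = R² Δλ (sin φ_top − sin φ_bot)` — about 85.9 km² for a 5′ cell at the
equator, decreasing strictly with |latitude|; the 36 five-minute cells
inside a 30-minute cell sum to its area to machine precision. Coarse 30′
covariates are block-downscaled: every 5′ centre inherits its parent cell's
value; a centre outside coverage or in a missing cell is an error naming
the pixels, never silent NaN propagation.

## Sample construction

Pixels flagged as urban or protected are removed before estimation (a unit
losing all pixels is an error). Units are kept when every crop of interest
holds at least a minimum share of land (inclusive threshold, default 0.5%)
and the crop shares jointly sum to at most 1; the sum cap is applied to
*raw* reported shares, before the base-category residual is formed, because
jointly over-unity shares (multiple cropping seasons, data inconsistencies)
cannot be represented as a composition at all. Observed share denominators
are treated as upstream: `AggregateShares` takes fractions as given.

## Prediction, calibration, validation

Raw predictions apply the fitted softmax to any pixel table carrying the
design covariates (out-of-sample grids included). Level-1 calibration
multiplies every pixel fraction in unit `j` by `r_jk = y_jk / H_jk`, after
which unit aggregates equal the observed shares exactly — unless a pixel
fraction would exceed 1, in which case it is capped at 1 with a warning and
the unit's shortfall recorded. No redistribution is attempted: capping
rules are not identified by the data, and the transparent rule keeps the
scaled grid interpretable as "per-crop calibrated" (per-pixel sums across
crops may then deviate from 1). Scaling preserves the within-unit ranking
of pixels.

Validation metrics: RMSE over units; OLS calibration of observed on
predicted shares with conventional standard errors and t-tests against
intercept 0 / slope 1 (this regression direction makes the ideal fit the
45-degree line with predicted on the horizontal axis; the direction is
exposed as a switch); R² as the squared Pearson correlation. Level-2
validation aggregates the *calibrated* grid to whichever district units
have observed data — partial coverage simply reduces `n_units`, which the
report records. The naive baseline assigns every pixel its Level-2 unit's
observed share; aggregating it returns those shares identically, and in a
world where truth is unit-constant it is exact while the covariate model
generally is not — the test suite checks both directions of that
comparison.

## Synthetic data

The generator emulates the estimator's assumed data structure, not any
particular real landscape: pixels nested in units (with optional Level-2
districts), covariates drawn as unit random intercept + pixel noise with a
configurable variance split (default half/half), clipped to bounds;
latitudes assigned per unit with small pixel jitter; areas from the
spherical formula; Bernoulli exclusion flags. Regional presets carry
means/SDs/bounds typical of North, Central and South American
growing-season climatologies and soils (e.g. North America: temperature
mean 16.66 °C, SD 6.09). Clipping (rather than resampling) at the bounds
shaves a few percent off the realised SD and shifts means by well under a
tenth of an SD; tests budget for this explicitly.

Observed shares come from the model's own forward map. Noiseless mode
returns `y = H(β_true)` bit-for-bit, giving the estimator an exact
recovery target. Dirichlet mode draws `y_j ~ Dirichlet(c·H_j)`: mean-
preserving — exactly the conditional-mean assumption the QMLE needs — with
concentration `c` setting signal-to-noise. The noise sits at the unit
level because the likelihood treats unit shares as the observable; it is a
testing device, not a claim about how real census shares deviate from the
mean. Consequences for interpretation: passing recovery/coverage tests
shows the estimator is correct *under its own assumptions*. The generator
does not emulate spatially autocorrelated covariate fields beyond unit
clustering, reporting gaps, year mismatches across countries, or
measurement error in the covariates, so the tests say nothing about
robustness to those.

## Problem sizes and tolerances in the test battery

Synthetic checks run at J = 200 units of 3-8 pixels (recovery, coverage,
bootstrap agreement), 100 Dirichlet replicates at concentration 500 for
coverage, B = 200 bootstrap replicates, and smaller instances (J = 5-80)
for the gradient and reduction oracles — sizes at which every property is
sharply testable while the full suite stays fast. Gradient-oracle
tolerance is 1e-6 relative against central differences; noiseless recovery
1e-3 absolute; conservation identities 1e-12 (pixel/unit share sums) and
1e-10 (post-calibration aggregates); covariance agreement 25% on standard
errors. The consistency property (estimation error shrinking in J) uses 40
replicates at J ∈ {25, 100, 400}, comparing root-mean-squared error rather
than bias, which is far better behaved at moderate replicate counts.

## Interfaces and limitations

Delimited text throughout: pixel tables (CSV; areas derived from latitude
when absent), long-format shares, long-format prediction grids, YAML design
specs, JSON fit documents embedding version/seed/config-hash. No raster
(GeoTIFF) ingest/export and no figure generation — the validation report
exports scatter data (predicted, observed, unit) for external plotting
instead. The panel / correlated-random-effects extension of the estimator
is out of scope, as are elasticity variants of the effects and any
redistribution scheme for capped pixels.
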