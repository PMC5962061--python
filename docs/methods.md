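# Methods

## Sampling model and assumptions

The package implements two-stage density surface modelling for strip
transects. Stage one assumes certain detection: every animal group whose
perpendicular distance to the flight path is at most half the bandwidth
(default 1400 m / 2) appears in the photo record, and nothing outside
does. There is no detection-distance falloff and no movement model; the
record's photo position, not the aircraft position, is what enters the
analysis. Stage two treats the per-segment counts as conditionally
independent Tweedie variables given the covariates (until the residual
diagnostics say otherwise, see AR(1) below).

Segments are consecutive arc-length slices of the path, one bandwidth
long, so a full segment's strip is an approximately square 1.96 km²
effort unit. A terminal remainder shorter than `min_fraction` × bandwidth
(default 0.5) is dropped; a kept remainder carries its true, smaller area
into the offset, which keeps partial segments statistically valid. A
record exactly on the boundary between two segments goes to the lower
order index; where consecutive strips of a curved path overlap, the
along-track nearest segment wins. Segments and prediction cells use the
same covariate summarizer (area-weighted raster means over the footprint,
centroid distance to coast) and the same ≥ 95 % forest-cover exclusion.

## Smooths and penalties

Univariate smooths (elevation, distance to coast) are cubic B-spline
bases with knots at the quantiles of the observed covariate and the
exact integrated-squared-second-derivative penalty (two-point
Gauss–Legendre per knot span, which is exact for the piecewise-quadratic
integrand). The penalty null space is {constant, linear}.

The geographic-location smooth is a low-rank isotropic radial smoother:
coordinates are standardized, `k − 3` knots are chosen by deterministic
farthest-point sampling (starting nearest the centroid; prefixes are
nested, so bases for increasing `k` nest too), the basis is
{1, x, y, Gaussian kernel columns} with lengthscale set to the median
inter-knot distance, and the penalty is the kernel Gram matrix at the
knots — positive semidefinite by construction, with the plane
{1, x, y} as its null space. We chose this over a thin-plate kernel
(r² log r) because the raw thin-plate Gram matrix is indefinite without
side conditions, while the kernel form gives the same qualitative
behaviour (isotropy, exact plane reproduction) with a clean quadratic
penalty. The optional joint location-by-covariate smooth ("AA:GL",
"DC:GL") is the same construction on standardized (x, y, covariate)
triples; it degenerates (by design, with a clear error) when the third
input is an exact linear function of location.

Every term absorbs a sum-to-zero constraint over its training data, so a
`k`-dimensional term contributes `k − 1` columns next to the model
intercept. Penalty matrices are rescaled to unit Frobenius norm at
construction (the raw curvature Gram is recoverable via
`penalty_scale`); this makes smoothing parameters dimensionless and
keeps the λ search well conditioned whatever the covariate units —
meter-scale covariates otherwise push useful λ values beyond 1e12.

## Fitting and smoothing selection

Coefficients minimize the penalized Tweedie deviance by Fisher-scoring
IRLS on the log link with the `log(area km²)` offset; steps are halved
when they fail to reduce the penalized deviance, and convergence
requires both a relative deviance change below 1e-8 and a stable
coefficient vector, within 200 iterations. The default Tweedie power is
p = 1.5; p = 1 is accepted as a Poisson boundary (used by the oracle
tests), and a profile over a p grid can be run through the candidate
machinery. The dispersion φ is estimated from the Pearson statistic at
convergence, and the coefficient covariance conditional on λ is the
Bayesian form φ(XᵀWX + S_λ)⁻¹.

The smoothing criterion is a Laplace / extended-quasi-likelihood
approximation to the restricted marginal likelihood:

    V(λ) = [D + βᵀS_λβ] / (2φ̂) + ½ Σ log(2πφ̂ (y_i + 1/6)^p)
           + ½ log|XᵀWX + S_λ| − ½ log₊|S_λ| − (M₀/2) log φ̂

with φ̂ = (D + βᵀS_λβ)/(n − M₀) profiled in closed form and M₀ the total
penalty-null-space dimension. Lower is better. λ is searched on the log
scale: a 7-point grid multistart (10⁻³…10⁵, shared across terms) seeds a
Nelder–Mead polish, clipped to log λ ∈ [log 10⁻⁶, log 10⁸] because the
criterion is flat beyond full shrinkage and unbounded search only
degrades conditioning. Basis dimensions can be searched coordinate-wise
over a `k_grid` within [4, 20]; ties in the score break toward fewer
effective degrees of freedom. Everything is deterministic.

On pure-noise covariates this criterion shrinks the smooth away (grid
argmin at the largest λ) in about 85 % of replicates, matching what
mgcv's REML does on identical data; REML's point mass at λ = ∞ under
the null is intrinsically below one, so the tests assert the measured
rate and that the selected effective degrees of freedom sit at the
penalty null space, not a 100 % rate.

## Candidate set, autocorrelation and correction

Per season the candidate structures are AA+GL, DC+GL, GL, AA, DC and
optionally AA:GL / DC:GL; AA and DC additionally share a model only when
their Pearson correlation falls below the 0.4 screen (on the generated
coastal terrain it does not: the landscape is calibrated to
|r| ≈ 0.65). Candidates are ranked by the REML-type score.

Residual autocorrelation is diagnosed on deviance residuals at lags of
one and two segments (1400 / 2800 m), pooling contiguous within-transect
pairs across transects; cross-transect pairs never enter. The correction
triggers exactly when any lag correlation exceeds 0.15. The corrected
fit whitens the working model with an AR(1) correlation among
consecutive segments within each transect. ρ is estimated by a damped
fixed point on the lag-1 residual correlation, run at the smoothing
parameters selected under independence (re-selecting λ inside the loop
makes the estimate jitter); smoothing is re-selected once at the settled
ρ. Because the estimator reads the correlation off deviance residuals,
observation noise attenuates it relative to the latent link-scale
correlation; the recovery studies therefore use a strong latent field
(σ = 1.2 on the link scale, mean counts ≈ 40 per segment), under which
the mean estimate lands within ±0.1 of the truth. After correction,
smooth terms whose Wald-type test (term coefficients against their
conditional covariance, χ² on the term's effective df) gives p ≥ 0.05
are dropped and the model refitted — mirroring the elimination of a
location term that loses significance under correlation.

## Prediction and uncertainty

The prediction grid is anchored at the landscape origin, keeps only
full-area cells (all equal to the configured 1.96 km²), and applies the
forest exclusion. Per-cell abundance is exp(η̂_c) × area. Cells whose
covariates fall outside the fitted range are flagged as extrapolation,
never censored — their inflated CVs are the honest signal. Beyond the
training range a cubic smooth is continued constant at its boundary
value (cubic polynomial extrapolation is unbounded and would dominate
totals through the exponential link); radial terms decay naturally
toward their polynomial part.

Delta-method uncertainty conditions on the selected λ
(smoothing-parameter uncertainty is ignored, as in standard density-
surface practice): Var(N̂_c) ≈ N̂_c² x_cᵀ V x_c per cell and
aᵀ(X_p V X_pᵀ)a for the total, with the full between-cell covariance.
The posterior-simulation option draws coefficients from N(β̂, V) with a
fixed seed; at design scale the two total CVs agree within about 1 %.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes:
a smooth elevation field correlated with distance to coast at a
configurable target (default 0.65, implemented by mixing a standardized
coast gradient with an orthogonalized Gaussian random field, then
clipping to 0–1400 m), patchy forest from a logistic-squashed smooth
field, group placement by an inhomogeneous Poisson process with
log-linear smooth effects, zero-truncated negative-binomial group sizes
(mean 4, shape 2 by default — grouped and overdispersed; a point mass at
1 is available for exact oracles), and certain-detection strips with
monotone timestamps. The default coastline is one straight boundary
edge, which makes distance-to-coast analytic.

It does not emulate: observer error or double counting, daily
forest/pasture movement (animals are where the intensity says),
photogrammetric bandwidth estimation, irregular coastlines, or
covariate measurement error. Passing tests therefore demonstrate that
the estimation machinery recovers truth under its own assumptions — not
that those assumptions hold in any particular field campaign.

All randomness flows from one root seed through `SeedSequence` spawning
(landscape, population, survey as separate streams), so realizations
are bit-reproducible.

## Study designs behind the reported numbers

* Desk arithmetic: the per-survey effort/record/count table of the
  motivating campaign is transcribed as input; totals are recomputed
  through the record-accounting path. The study-area geometry is
  realized as a 49 × 74 grid of 1.96 km² cells (7,106.96 km², the
  printed 7,107 rounded) with exactly 211 cells ≥ 95 % forest.
* Abundance recovery: 50 simulated surveys on an 84 × 84 km landscape,
  10 transects × 60 segments = 600 segments, known quadratic elevation
  effect, group-size mean 4. Reported: median |Σ fitted − detected| /
  detected (≈ 2 %) and the pooled fraction of evaluation points — 40
  covariate quantiles spanning the central 95 % of the sampled range —
  where the true (centered) smooth lies inside the fitted pointwise 95 %
  band (≈ 95 %). Quantile spacing weights the check by where the data
  actually constrain the fit.
* AR(1): ρ = 0 refit equals the independent fit to machine precision;
  ρ = 0.4 recovery over 20 replicates of 12 transects × 40 segments.
* Uncertainty: delta vs 10,000-draw posterior total CV on one
  design-scale fitted surface.

These problem sizes keep the full suite and the acceptance script at
about a minute each on one CPU while leaving the Monte-Carlo margins
comfortable.

## Known limitations

* The REML-type score is an EQL/Laplace approximation, not the exact
  Tweedie restricted likelihood; scores are comparable across candidates
  and p values but not numerically interchangeable with other software.
* Fitted-total conservation (Σ fitted ≈ Σ observed) holds only
  approximately for Tweedie with log link — typically within a few
  percent on well-specified fits, and asserted as such, never exactly.
* The fixture-scale pipeline (~42 segments/season) carries
  single-realization errors of tens of percent; that is a property of
  the design size, and the recovery tolerance documented for it (50 %)
  is a smoke bound, not an accuracy claim.
* AR(1) ρ is estimated on the deviance-residual scale and is attenuated
  toward zero when observation noise dominates the latent field.
* No anisotropic (tensor-product) smooths, no spatial covariance
  families beyond within-transect AR(1), no map rendering beyond the
  CSV/ASCII-grid exports.
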