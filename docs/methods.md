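# Methods

## Windowing

Locations are partitioned into contiguous, half-open windows
[origin + k·width, origin + (k+1)·width). A fix exactly on a boundary
belongs to the later window, so the partition is exhaustive and
exclusive. Empty or under-sampled windows are retained with a missing
overlap value rather than dropped, keeping the dyad's two series
index-aligned; the regression likelihood later evaluates the ARMA
correlation at the *true* lags across such gaps instead of re-indexing,
which would misstate dependence. Timestamps are parsed in a
caller-stated timezone; the window origin is a required argument because
nothing in the data determines whether weeks should be calendar- or
deployment-anchored.

## Utilization distributions

Each window UD is a fixed-bandwidth KDE with an isotropic bivariate
normal kernel and the bivariate reference (normal plug-in) smoothing
parameter h = sqrt((s²x + s²y)/2)·n^(−1/6) (sample variances, n−1
denominator). The n^(−1/6) rate is the bivariate convention used by
standard home-range software; it is not Silverman's univariate n^(−1/5).
The interface accepts any externally chosen h, but only the reference
rule is implemented: plug-in/cross-validated and movement-model
bandwidths are out of scope.

Both members of a dyad are evaluated on one shared grid (default
150×150) covering the union bounding box of their fixes padded by 3·h on
every side, so the overlap integral is defined without resampling.
Because a finite grid truncates the kernel's infinite support, each
surface is renormalized to unit mass on the grid; pre-normalization mass
exceeds 0.99 at the default padding, and renormalization keeps
self-overlap at exactly 1. The kernel sum is computed separably (an
outer product of per-axis Gaussian matrices), which makes a 150×150
evaluation with 1000 points a few milliseconds instead of seconds.

Defaults, all exposed in configuration:

| parameter   | default | meaning                                         |
|-------------|---------|-------------------------------------------------|
| resolution  | 150     | grid cells per axis (shared dyad grid)          |
| padding     | 3       | grid margin in multiples of the larger h        |
| min_points  | 30      | fewest fixes per window to attempt a UD         |

Windows with fewer than `min_points` fixes for either animal yield a
missing overlap value: too few locations cannot support a meaningful UD
at any bandwidth.

## Overlap

Bhattacharyya's Affinity BA = ∬√(f·g) is evaluated by cell-centre
(Riemann) quadrature on the shared grid and clipped to [0, 1]
(renormalized surfaces can exceed 1 by ~1e−9 in floating point).
Quadrature at the default settings agrees with the closed-form Gaussian
value exp(−d²/8) to better than 1e−3 across separations d ∈ [0, 4].
Mismatched grids are a hard error — silent interpolation would change BA
irreproducibly. The joint-volume surface √(f·g), whose integral is BA,
is exposed for mapping where joint use occurs. Other overlap indices
(UDOI, PHR) and significance tests of a single BA value are out of
scope.

## Copula beta regression

The margin is Beta(μ_t, κ) with shapes (μκ, (1−μ)κ), logit link for μ
and a constant precision κ on a log scale (the fitting surface has a
hook for a dispersion design matrix, but constant κ is the model).
Dependence is a Gaussian copula whose latent correlation is the ACF of a
stationary, invertible ARMA(p, q) process. For a continuous margin the
likelihood is exact:

    ℓ = Σ_t log f(y_t) + log φ_n(z; 0, R) − Σ_t log φ(z_t),

with z_t = Φ⁻¹(F(y_t)). With p = q = 0 the copula term cancels
identically and ℓ reduces to the independent beta-regression likelihood
(verified in tests against a separately coded maximizer). The ARMA ACF
is computed via statsmodels' autocovariance recursion; the ARMA(1,1)
closed form ρ₁ = (1+ψλ)(ψ+λ)/(1+2ψλ+λ²), ρ_k = ψρ_{k−1} serves as an
independent oracle in tests, alongside a dense multivariate-normal
evaluation of the whole likelihood on short series.

Numerical choices:

- **Constraints.** ARMA parameters are optimized unconstrained as tanh
  of partial autocorrelations mapped through the Durbin–Levinson
  recursion (for p = q = 1 this is simply tanh⁻¹ of the coefficient),
  which enforces stationarity and invertibility exactly.
- **Start values.** β from least squares of logit(y) on X; κ by method
  of moments from the residual variance; ARMA at zero. The independence
  fit is a consistent starting point.
- **Boundary responses.** y ∈ {0, 1} lie outside the open beta support
  and are clamped to [1e−6, 1 − 1e−6] with a logged count.
- **Uncertainty.** Observed information by central differences with
  step 1e−5·(1+|θ|), inverted and delta-method–mapped to the natural
  scale (β, κ, ψ, λ). An information matrix that is indefinite or has
  condition number above 1e10 is reported as "vcov unavailable" rather
  than silently pseudo-inverted; the classic case is an ARMA(1,1) fit to
  serially independent data, where ψ and λ cancel along a common-root
  ridge. Reported P-values are Wald tests.
- **Non-convergence** is a flag on the result, not an exception; the CLI
  maps it to exit code 3.

Effect sizes are reported on the response scale,
logistic(x_toᵀβ) − logistic(x_fromᵀβ), because a change in mean overlap
is the ecologically interpretable quantity; intervals by the delta
method (default) or a parametric bootstrap of β. Decorrelated residuals
L⁻¹z (L the Cholesky factor of the latent correlation at observed lags)
are approximately i.i.d. standard normal under a correct specification
and feed ACF/PACF diagnostics with ±1.96/√n bands.

## Simulation study

The generator holds each animal's true UD constant within two regimes:
circular bivariate normal with σ = 1, means separated by 3.580 before
window 50 and 1.319 from window 50 on, over 100 windows — i.e. true
overlap steps from exp(−3.580²/8) = 0.2015 to exp(−1.319²/8) = 0.8045,
a 0.60 change. Within each window a fixed number of locations is drawn
i.i.d. from the true UD of each animal. The i.i.d. draw is deliberate:
it makes the within-window sample an exact draw from the distribution
whose overlap is being estimated, isolating estimator error from
movement autocorrelation. Consequently the generator does **not**
emulate serially autocorrelated fixes, irregular fix success,
measurement error, or non-Gaussian UD shapes — passing tests bound
estimator behaviour under ideal sampling, not under any particular
field protocol.

Each replicate re-estimates the 100-window BA series through the full
KDE + quadrature pipeline and fits the regression with the known step
covariate. Because windows are generated independently, the replicate
fit defaults to p = q = 0; ARMA(1,1) is available by option. Bias is
mean(estimate) − truth with the Monte-Carlo standard error sd/√reps;
per-level BA bias pools all pre-change (true 0.2015) or post-change
(true 0.8045) windows across replicates. The sampling-error summary is
the SD of window-level BA estimates around their per-level means,
pooled over levels.

Replicate streams are seeded as (base_seed, intensity, replicate), so
results are bit-reproducible and adding intensities or replicates never
perturbs existing draws.

Problem sizes in the shipped acceptance run: 50 replicates at 50
locations/window (bias at both levels, effect-size bias), 20 replicates
each at 150 (sampling error), 200 and 1000 locations/window (bias
sweep); each replicate is a full 100-window series. The whole run takes
a few minutes on one CPU.

## Known limitations

- Only the reference bandwidth is implemented; it oversmooths complex
  (non-Gaussian) UDs, and the known consequence — inflated density in
  the tails — is visible in the simulation as a small positive bias of
  low overlap values and a corresponding small negative bias of step
  effects.
- Constant precision κ; dispersion covariates are not modelled.
- One dyad per analysis; multi-dyad (multivariate) series, hierarchical
  measurement-error models and change-point detection are out of scope.
- Coordinates must be planar; no reprojection is performed.
- Discrete or boundary-inflated margins (exact zeros/ones beyond the
  clamp rule) are not modelled.
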