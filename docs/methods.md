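# Methods

This note records the statistical model, the pinned defaults, the
numerical choices, and the known limits of the package's synthetic
evaluation. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model

Plot-level richness counts follow a hierarchical Poisson regression
with a log link:

    y_ij ~ Poisson(λ_ij),   λ_ij = exp(β₀ + Σ_m β_m X_mij + u_j + ω_ij)

with plot *i* inside 1-km national-grid square *j* (square identity by
floor division of planar metre coordinates by 1000; square centroid at
the square origin + 500 m). `u_j ~ N(0, θ²)` captures within-square
similarity; `ω` captures broad-scale spatial autocorrelation as a
stationary Matérn field with smoothness ν = 1.

### Covariate preparation

Raw covariates are divided by fixed divisors so that a coefficient is
"change in log richness per 100 m of altitude / 250 mm of rain / 0.5 pH
unit / 10° of slope / 200 mg kg⁻¹ of aluminium / 10 mm of soil-moisture
deficit / 10 sheep per year". No centring or unit-variance scaling is
applied: divisor units keep coefficients comparable across studies,
which standardisation would break. Rescaled values are reported at 2
decimals; internal computation keeps full precision. Collinearity is
*screened and reported* (all pairs above a threshold, sorted by |r|),
never acted on automatically — the collinear pollutant pair is the
scientific question, and stepwise selection is deliberately not
implemented. Missing values are mean-imputed (the only policy in
scope). Four strongly inter-correlated climate variables can be
compressed by PCA on the correlation matrix (the block mixes mm and
°C, so the correlation metric is the scale-invariant choice), keeping
two components; each component's sign is fixed so its loading on the
first input column is non-negative, making scores reproducible. VIFs
use the classical definition (auxiliary OLS of each column on all
others plus an intercept); an optional grouped mode additionally
conditions on square-level means as a linear stand-in for
random-intercept-model VIFs, whose exact definition varies between
implementations. Grazing intensity (low/medium/high) is
treatment-coded with "low" as reference.

One documented inconsistency: for the clustered-study precipitation
range 604.9–1773.3 mm with divisor 250, the arithmetic gives
2.42–7.09; a published table prints the lower endpoint as 0.42, which
is inconsistent with its own divisor and treated here as a typo. The
package always reports the arithmetic value.

### SPDE field

The Matérn ν = 1 field is the FEM solution of
(κ² − Δ) x = W/τ on a Delaunay mesh, giving the sparse precision

    Q = τ² (κ⁴ C + 2 κ² G + G C⁻¹ G)

with lumped (diagonal) mass matrix C — C⁻¹ stays diagonal so Q stays
sparse — and P1 stiffness matrix G. Range ρ = √8/κ (correlation ≈ 0.13
at d = ρ); marginal sd σ = 1/(√(4π) κ τ). Smoothness is fixed at
α = 2 (ν = 1); other orders are out of scope.

Mesh construction: Delaunay triangulation over the centroids of the
occupied 1-km squares, surrounded by graded concentric rings of points
whose spacing grows geometrically (factor 1.5) from the interior edge
length to the coarse outer limit, out to a boundary ring at
`boundary_extension_fraction` (default 0.15) of the domain diameter
beyond the data hull. The grading avoids abrupt fine-to-coarse element
transitions, and the extension pushes the Neumann boundary artefacts
(variance inflation near the hull) away from observations. Default
edge limits: 10 × grid size inside the data hull, 40 × grid size in
the extension; all configurable, and mesh summaries (node count, edge
lengths) are exposed because results can be mildly mesh-sensitive.
Discretisation accuracy scales with h/ρ (mesh edge over range): the
marginal-variance inflation of the lumped-mass GMRF is ≈ (hκ)²/2, so
meshes with h ≲ 0.1 ρ keep correlation errors under ~5%. Fits may use
coarser meshes when the field is a nuisance component; simulation
*always* resolves the generating range (edges ≈ ρ/5 by default),
since an under-resolved generating mesh would produce spurious
short-range noise instead of a smooth field.

Sparse N(0, Q⁻¹) sampling and log-determinants use SuperLU in
symmetric mode (no pivoting, fill-reducing symmetric permutation),
giving L·√D as a Cholesky factor of the permuted matrix; a dense
Cholesky is the fallback for small or awkward matrices.

### Priors (pinned)

"Package default" priors are version-dependent in other software, so
this package pins its own and records them in every fit:

| parameter | prior | default |
|---|---|---|
| fixed effects β_m | Normal(0, precision 0.001) | |
| intercept β₀ | flat (precision 0) | |
| square-effect log-precision | log-gamma(shape 1, rate 5e-5) | weakly informative, favours small θ² |
| SPDE (log κ, log τ) | independent Normals, sd 1.5 | centred so prior median range ≈ 20% of the domain diameter and prior median σ ≈ 1 |

The log-gamma square prior concentrates on large precisions when the
likelihood is uninformative; fits therefore flag
`theta2_prior_dominated` when the profile likelihood along that axis
moves by less than 1 nat across the exploration grid, which is exactly
the situation of one-plot-per-square designs.

### Inference

Conditional on hyperparameters ψ (square log-precision and/or SPDE
log κ, log τ), the latent vector (w, u, β₀, β) has a log-concave
posterior; its mode is found by damped Newton iteration (sparse
assembly of Bᵀdiag(λ)B, dense Cholesky solves, backtracking line
search, linear predictor clipped at ±30 to avoid overflow). The
Laplace approximation of log p(y | ψ) is maximised over ψ by
Nelder–Mead; per-axis posterior scales are then measured by profiling
(walk out until the log posterior drops 2 nats — robust where an axis
is nearly flat), cross-curvature is estimated by finite differences in
those scaled coordinates, and a tensor grid (default 5 points per
dimension over mode ± 2.5 sd) is laid out in the *principal axes* of
that curvature, because the (log κ, log τ) posterior lies on a narrow
ridge that an axis-aligned grid integrates badly. If more than 10% of
the grid weight lands on the boundary, the grid is widened (up to
twice) and recomputed. Fixed-effect marginals are Gaussian mixtures
over the grid, with a third-order mean correction
δ_i = −½ Σ_n λ_n W_in c_n (W = H⁻¹Bᵀ, c the predictive variances)
that moves each conditional mode toward the conditional mean — the
Poisson log-likelihood is skewed in η, so the mode alone overshoots.
Quantiles come from bisection on the mixture CDF. Full nested
(INLA-style) marginal-likelihood corrections are intentionally not
implemented; an importance-sampling check during development showed
the Laplace marginal accurate to ~0.2 nat on the grids used here, and
the MCMC agreement test is the permanent guard.

The MCMC cross-check is a one-block independence sampler: propose ψ′
by a random walk scaled to the Laplace ψ-covariance, then propose the
full latent vector from the Laplace Gaussian at ψ′, and accept both
jointly by exact Metropolis–Hastings. This is an exact sampler (the
Laplace Gaussians only shape proposals), typically accepting 25–70%.
Split-chain R-hat and a lag-1 ESS on the intercept are reported;
non-convergence flags the result rather than hiding it.

Every stochastic path takes an explicit seed (default 20100429); the
Laplace route is fully deterministic given its settings.

### Diagnostics

* **DIC** = D̂ + 2 p_D with D̄ from posterior draws of η and the
  plug-in D̂ at the posterior *mean of η* (not of λ): the hierarchical
  convention that keeps p_D ≥ 0 in practice; negative p_D is still
  reported and flagged.
* **Variance partition**: empirical variance of the posterior-mean
  field at plot locations vs the posterior-mean square effects at
  plots; `percent_structured` to 1 decimal. This is one defensible
  definition among several (posterior variances or hyperparameter
  estimates would be alternatives); it is stated explicitly so the
  number is interpretable.
* **Partial effects**: joint posterior draws of (β₀, β_cov) — 4000 by
  default, seeded — evaluated as exp(β₀ + β_cov x) on the 0th–100th
  decile grid of the covariate, other covariates at zero (so levels
  are baseline-plot predictions, deliberately low). At x = 0 the curve
  is exactly the posterior of exp(β₀).

## Synthetic data

The generator emulates the two study designs: `scattered` (883 plots
by default, with ~15% of plots doubled into an already-occupied 1-km
square, since real surveys record multiple plots per square) and
`clustered` (68 sites × 5 plots inside a 100 × 100 m block per site;
an "archived" variant drops 20 random plots to 320). Covariates are a
Gaussian copula with target Pearson correlations — the pollutant pair
at r = 0.83 (clustered) or r = −0.70 (scattered) — mapped through a
rank-preserving affine transform onto the published covariate ranges;
the transform is affine per column, so the target correlations are
preserved exactly in expectation. Effects are set on the rescaled
scale; the intercept is derived from a target mean richness (25 by
default, 16/12 in the presets, matching quadrat-scale acid-grassland
richness). The spatial field is sampled from the SPDE GMRF on a
simulation mesh that resolves the generating range; square effects are
iid normal; vascular counts are Poisson, and a bryophyte component
(same drivers, ~15% of the vascular rate) is added for the combined
response, keeping the total Poisson.

Preset field parameters (range 60–80 km, σ ≈ 0.25, θ² = 0.01–0.02) are
plausible magnitudes chosen once for the emulation — the original
studies' field parameters are available only as posterior maps and are
not reproduced here. Everything generated is labelled synthetic.

**What the synthetic evaluation does and does not show.** Passing
recovery and agreement tests demonstrates that the estimator is
approximately calibrated *under the model's own assumptions* (correct
link, Poisson noise, linear effects, stationary isotropic field,
covariates without measurement error or spatial structure). It cannot
detect misspecification risks of real surveys: nonlinear or unimodal
richness responses, pollutant measurement error at 5 × 5 km grain,
spatially structured covariates confounded with the field, surveyor
error, or non-random site selection. Those caveats transfer directly
to any real-data use.

## Problem sizes and numerical defaults

Test-suite and acceptance runs use deliberately economical sizes
chosen as good experimental design at desk scale: recovery uses 50
replicates of the 340-plot clustered design with a ~20 km fit mesh and
a 3-point hyperparameter grid (the field is a nuisance there); the
DIC comparison uses 20 replicates of 150 scattered plots with a strong
field (σ = 0.6, θ² = 0.005), where spatial pooling is genuinely
informative; the Laplace-vs-MCMC agreement check uses 150 plots in 30
sites with well-identified variance components (θ² = 0.15, σ = 0.5) so
that it measures approximation error rather than random-walk wandering
along a weakly identified ridge; the Matérn-correlation oracle uses a
strip-shaped equilateral lattice (h = 0.07 ρ, ≤ 500 nodes) against the
closed form (κd)K₁(κd) via dense inversion. Degenerate inputs
(non-integer counts, all-missing columns, constant covariates,
collinear duplicates, locations outside the mesh hull, non-PD
correlation targets) raise informative errors rather than propagating.

## Known limitations

* Empirical-Bayes Laplace, not full nested inference: hyperparameter
  uncertainty enters only through the grid; funnel-shaped ψ posteriors
  (weakly identified θ² with a flexible field) are integrated
  approximately, and fixed-effect medians can shift by ~0.1 posterior
  sd relative to exact MCMC in those regimes. The prior-dominance flag
  marks them.
* One spatial resolution per fit: no non-stationarity, anisotropy,
  barriers, or spatio-temporal extension; Poisson only (no
  negative-binomial or zero inflation).
* DIC is the only comparison criterion (by design); WAIC/LOO are not
  provided.
* The GLMM-style VIF used in some published screenings has no single
  definition; the classical VIF is the default here and the grouped
  variant is an approximation, not a reproduction.
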