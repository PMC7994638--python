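# Methods

## Movement model

Observed tracks are reduced to per-step observations: step length `ℓ_t`
(Euclidean distance between consecutive fixes, metres) and turning angle
`φ_t` (signed heading change, counterclockwise positive, wrapped to
(−π, π] with +π at the boundary).  A K-state hidden Markov model assumes
that, conditional on a latent behavioral state `S_t`, the two streams are
independent with

- `ℓ_t | S_t = k ~ Gamma(mean μ_k, SD σ_k)` — internally shape
  `(μ_k/σ_k)²` and rate `μ_k/σ_k²`;
- `φ_t | S_t = k ~ wrapped Cauchy(μφ_k, ρ_k)`, density
  `(1/2π)(1−ρ²)/(1+ρ²−2ρ cos(φ−μφ))`, `ρ ∈ [0,1)`.

The first step of every burst has no defined turning angle; its angle term
is simply omitted from the likelihood (encoded NaN).  Exact zero step
lengths have no gamma density and are rejected by default; an optional
zero-inflated variant adds a per-state point mass `π0_k` for data where
collar jitter has been rounded away.

Transitions follow a row-wise multinomial logit with the diagonal as
reference.  Hour of day `h` (fractional clock hour of the step's starting
fix) enters each off-diagonal logit as a first-order cosinor,
`β0 + βc cos(2πh/24) + βs sin(2πh/24)`.  A cosinor is used because clock
time is circular — a linear "hour" effect would place a discontinuity at
midnight; a linear-in-hour form and a constant form remain available
(`transition_covariate="hour"` / `"none"`).  The initial distribution δ is
estimated (shared across bursts and animals within a stratum) rather than
fixed at the stationary distribution.

### Estimation

The forward-algorithm log-likelihood (scaled, restarting at δ at each
burst) is maximized over an unconstrained working scale: log μ, log σ,
logit ρ, μφ = 2·atan(x), raw transition coefficients, and multinomial
logits for δ.  The gradient is computed analytically via the Fisher
identity — the score equals the posterior expectation of the
complete-data score, obtained from one forward–backward sweep — and
optimization uses L-BFGS-B.  Convergence requires the relative
function-change criterion (1e−8) or a working-scale gradient norm below
1e−4 within 500 iterations; non-convergent starts are discarded with
their diagnostics retained.

Because the likelihood is multimodal, each fit draws 25 random
starting-value sets (configurable): state gamma means log-uniform within
a factor of 3 of quantile anchors of the observed steps (ranks spread
from the 25th to the 90th percentile), σ proportional to the drawn mean
(×U(0.5, 1.5)), ρ ~ U(0.05, 0.9), μφ at 0 or π, transition intercepts
U(−2, −1) (mildly diagonal-dominant), diel coefficients 0.  The best
converged start is kept and states are relabeled by ascending gamma mean,
so state 1/2/3 always means resting/foraging/traveling.

Model order (2 vs 3 states) is chosen by AIC = −2 logL + 2k with k = 4K
emission parameters (+K with zero inflation) + K(K−1)·C transition
coefficients + (K−1) initial-distribution parameters; ties break toward
fewer states.  Decoding is global (Viterbi) in log space with ties broken
to the lowest state index.

Working-scale parameters are clamped inside the kernels (exponents to
±345, ρ to [1e−12, 1−1e−10]) so that line-search excursions return a
flagged non-finite likelihood instead of dividing by zero; such points are
simply rejected by the optimizer.

## Geometry and covariates

- **MCP / buffer** — convex hull of all fixes, dilated by 1.2 km with
  round corners (32 segments per quadrant; area error from arc
  discretization ≪ 0.5%).
- **Kernel home range** — bivariate isotropic normal kernel with the
  classical reference bandwidth `h = sqrt((var x + var y)/2) · n^(−1/6)`
  (one scalar bandwidth, sample variances).  The surface is a binned
  density (30-m cells, matching the landscape raster) smoothed by a
  Gaussian filter truncated at 6σ, padded 3.5 h beyond the fix bounding
  box, and renormalized to unit mass; binning displaces points by at most
  half a cell.  The 95% isopleth is the smallest cell set holding 95% of
  the mass (equivalently a density superlevel set); its realized mass is
  in [0.95, 0.96] by construction on any grid whose single-cell masses
  are small.
- **Systematic samples** — 90-m lattices (every third 30-m pixel)
  anchored at the raster origin, never at a random phase, so repeated
  samples coincide and lattice points correspond to pixel centres;
  membership tests are boundary-inclusive.
- **Distance covariates** — for land-cover classes, exact Euclidean
  distance transform between cell centres (0 inside the class); for
  streams and roads, point-to-segment distance from each cell centre to
  the polylines.  The two conventions differ by at most half a cell
  diagonal at the feature itself.
- **Standardization** — (x − mean)/SD computed on the combined
  used+available fitting set of each model, with the statistics stored so
  standardized coefficients can be reported per natural increment.
- **Collinearity screen** — pairwise Pearson correlations; for any pair
  with |r| > 0.6 the lower-priority covariate is dropped (priority order
  configurable; the default keeps distance-to-pine first).  The developed
  class is rasterized but excluded from the default covariate stack,
  reflecting its redundancy with the primary-road network.

## Selection models

Used–available logistic regression estimates the exponential RSF
`w(x) = exp(β'x)` up to an intercept that absorbs the sampling ratio; the
intercept is therefore never interpreted.  Second-order models are plain
binomial GLMs (statsmodels IRLS, observed-information SEs); rank
deficiency is reported with the aliased column names and separation as a
diagnostic error.  Third-order models add a per-animal normal random
intercept; the marginal likelihood integrates it out by adaptive
Gauss–Hermite quadrature (default 15 nodes, recentred at each group's
posterior mode and rescaled by the local curvature; one node reproduces
the Laplace approximation), and (β, τ) are maximized jointly with τ
bounded at 0.  Standard errors come from the numerical Hessian of the
marginal deviance.

Odds ratios per increment: with standardization SD `s`, the per-unit
coefficient is `β_std/s` and the reported ratio is
`exp(increment · β_std/s)` — increment 100 m for distances, 10 percentage
points for canopy.  The 95% CI transforms `β_std ± 1.96·SE` identically;
an interval containing 1 is flagged non-significant.  This composition
(rescale, then exponentiate) is one consistent reading of
"back-transform, exponentiate, and raise to the 100th power" and is
identical to exponentiating the coefficient re-expressed per 100 m.  AUC
is the rank-based concordance statistic (midranks; ties count ½).  No
multiple-testing correction is applied across the twelve third-order
models.  Decoded states are treated as known labels in the third-order
designs; state uncertainty is not propagated.

## Synthetic data

The generator emulates the study system the analysis was designed for:

- **Landscape** — a Gaussian random field smoothed to a 600-m patch scale
  and thresholded at the quantiles of the class weights (defaults ~50%
  upland pine, 25% bottomland hardwood, 10% shrub/herb, 8% upland
  hardwood, 3% developed, 4% other), giving contiguous patches whose
  realized proportions match the weights; streams and roads as
  random-walk polylines crossing the extent; canopy as a second smoothed
  field scaled to [0, 100] and elevated by 40 points inside forested
  classes.
- **Movement** — tracks simulated state-first from δ and Γ(h), then
  step/turn draws from the state's emission distributions, positions by
  heading accumulation (first heading uniform).  Default emission
  parameters are the published sex-by-season estimates for the three
  states; the wrapped-Cauchy concentrations are not published and are
  fixed once at (0.8, 0.6, 0.85) to reproduce the reported character of
  each state (tight reversal-dominated turning at rest and while
  foraging, near-straight traveling).  The default transition matrix has
  stay probability 0.8 (0.1 off-diagonal); pipeline simulations add a
  cosine diel modulation of amplitude 1 on the transition logits.
  Tracks are ballistic (habitat-free) and selection points are drawn
  point-wise, not as a biased walk: the two analyses estimate separate
  quantities, and coupling them in one simulator would conflate the
  estimands.  Simulated deployments start 48 h after the nominal
  deployment time, so the cleaning rule removes nothing from synthetic
  data by construction.
- **Selection** — used points by rejection sampling with acceptance
  ∝ exp(β'z(s) + b_animal) over uniform proposals, z standardized over
  the region's systematic grid.  The per-animal offset `b ~ N(0, τ²)`
  scales each animal's expected used-point count (Poisson around
  `n_used·exp(b)`), which is exactly what a random intercept absorbs in
  the used–available logit; the spatial distribution of each animal's
  points is unchanged by b, as it must be for a shared-β model.

Synthetic data reproduce the statistical structure the models assume —
they do not emulate GPS fix failure patterns, collar error (≈10–25 m in
the field), habitat-driven movement bias, or territoriality, so passing
recovery tests demonstrates correctness of the estimators under the
stated model, not robustness to real-data violations of it.

## Problem sizes and numerical checks

The test suite validates the likelihood and decoder against exhaustive
path enumeration (K ≤ 3, T ≤ 8, tolerance 1e−10), the GLMM marginal
likelihood against direct numerical integration (5-group toys, 1e−6),
AUC against exhaustive pair counting, and the distance transform against
brute-force nearest-target search.  Simulation-recovery checks use 30
tracks × 1,000 steps (emission means within 5%) and 40-animal selection
designs (~2,000 used points; coefficients within 3 SEs, Wald coverage in
[0.92, 0.98] over 200 replicates of n = 600).  The end-to-end model-grid
fixture uses 6 animals per sex–season at 600 steps with 6 starting sets —
large enough for AIC to select the generating 3-state structure in every
stratum — and is byte-reproducible from its single seed.

## Known limitations

- One HMM per sex–season pools animals; there are no random effects in
  the movement model.
- State-probability smoothing (forward–backward marginals) and
  pseudo-residual goodness-of-fit are not implemented; decoding is
  Viterbi-only.
- Coordinates must arrive in a projected metric CRS; the package performs
  no reprojection.
- The kernel home range supports only the single-bandwidth reference
  rule; no plug-in or cross-validated bandwidths.
- Burst gaps are handled by segmentation, never by imputation; tracks
  with pervasive missingness lose turning angles at every gap.
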