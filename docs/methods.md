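# Methods

## Model

Observed event counts per small area follow
`y_i ~ Poisson(E_i ρ_i)`, i = 1..n, where the expected count
`E_i = Σ_b rate_b · pop_ib` applies national per-person age-band rates
to area populations (indirect standardization), so a relative risk
`ρ_i = 1` means the national average and the whole-region standardized
ratio is 100 in expectation. The log relative risk decomposes as

```
log ρ_i = α + Σ_k f_k(X_ik) + s_i + h_i
```

with standardized construct scores `X_ik` (mean 0, sd 1 across areas).
The model family is the 3 × 4 grid of covariate-effect forms × area
random-effect structures:

* `f_k` **linear** (`β_k X_ik`), an **RW1 smooth** (one level per
  covariate bin under a first-order random-walk penalty), or a **cubic
  B-spline** (interior knots at the empirical 16.6/33.3/50/66.7/83.3
  percentiles, boundary knots at the score range).
* area effects **none**, **heterogeneity** (`h_i ~ N(0, 1/τ_h)` iid),
  **spatial** (`s` intrinsic CAR: `s_i | s_−i ~ N(mean of neighbouring
  s, 1/(τ_s d_i))`, `d_i` = neighbour count), or their additive
  **convolution** (BYM).

Identifiability: the ICAR field and the RW1 levels are invariant to a
constant shift, so both carry a sum-to-zero constraint (area-weighted
for RW1 bins) with the mean transferred to the intercept each MCMC
sweep; the spline basis drops its first column and centres the rest, so
each fitted curve has zero population mean. Consequently α always
estimates the national log relative risk of the analysed region.

### Priors

The defaults are the long-standing disease-mapping choices, exposed in
`PriorSpec`: intercept and regression coefficients `N(0, 1/10⁻⁴)`;
every random-effect precision (`τ_s`, `τ_h`, RW1 and spline smoothing
precisions) `Gamma(shape 1, rate 0.0005)`. Nothing in the pipeline is
sensitive to the fixed-effect prior at the data sizes used; the Gamma
rate matters mainly when a variance component is truly near zero, where
it mildly favours small but nonzero variances.

## Sampler

`fit` runs Metropolis-within-Gibbs with 2 chains (defaults 6,000
sweeps, 2,000 burn-in, thin 2; the test suite and acceptance script use
3,000/1,000, which the diagnostics show is ample at the lattice sizes
they fit). Updates per sweep:

* **α, β, spline coefficients** — scalar Gaussian random-walk
  Metropolis. Proposal scales adapt during burn-in only
  (Robbins–Monro toward 0.44 acceptance, gain decaying as 5/√batch),
  leaving the post-burn-in kernel fixed and valid.
* **s** — the lattice is greedily vertex-coloured; areas within a
  colour class are mutually non-adjacent, so their ICAR full
  conditionals are independent given the rest and can be
  Metropolis-updated as one vectorised block per class. A rook grid
  needs two colours.
* **RW1 levels** — the same scheme on the even/odd bins of the
  first-difference chain; empty bins are retained and bridged by the
  walk.
* **h** — fully vectorised single-site Metropolis (iid prior, no
  coupling).
* **precisions** — conjugate Gamma draws, e.g.
  `τ_s | s ~ Gamma(a + (n−1)/2, b + sᵀQs/2)` with Q the ICAR precision
  (rank n−1).

Starting values are data-driven (IWLS for fixed effects, smoothed
residual log-ratios for `s`, binned log-ratios for RW1 levels) so the
conjugate precision updates do not freeze random effects at zero in the
first sweeps; chains are jittered for overdispersion. The linear
predictor and its exponential are maintained incrementally and
recomputed every 500 sweeps to cancel floating-point drift.

Diagnostics: split-chain R̂ and an autocorrelation-based effective
sample size for every scalar parameter; a `ConvergenceWarning` (never
an error) is raised when any fixed effect's R̂ exceeds 1.05.

## Deviance and DIC

Deviance is the full `−2 log L` of the Poisson model including the
`log y!` term, recorded at every retained draw. Because the linear
predictor is linear in all sampled parameters, the deviance at the
posterior mean is evaluated at the running mean of the predictor, which
equals the predictor at posterior-mean parameters. Then
`p_D = D̄ − D(θ̄)` and `DIC = D̄ + p_D`; for a fixed-effects-only model
`p_D` reproduces the free parameter count to within sampling error.
Model comparisons use the standard thresholds: a DIC difference ≥ 3
favours the lower model, < 2 is inconclusive, and [2, 3) is reported as
`inconclusive_leaning` toward the lower model.

## Synthetic data generator

The generator is the package's test bed and emulates the statistical
structure of an English small-area suicide/self-harm study system:

* **Scale** — areas of ~7,600 residents (Gamma-distributed, cv ≈ 0.2);
  suicide at 10.1 per 100,000 per year and self-harm admissions at 190
  per 100,000, over a five-year window, giving mean expected counts of
  ≈ 3.8 and ≈ 72 respectively.
* **Construct scores** — one Gaussian factor per construct, four
  indicators loading equally in magnitude (one negative-polarity
  indicator per panel). Equal loadings λ give a leading-eigenvalue
  fraction `(1 + (p−1)λ²)/p`, inverted to hit the default variance
  fractions 0.79/0.77/0.68. Because a panel's leading-component score
  correlates with its factor at `λ/√(λ² + (1−λ²)/p) < 1`, the factor
  correlations are de-attenuated by that factor pairwise so the
  *scores* reproduce the target correlations (defaults 0.51, −0.47,
  −0.51) as n grows; the inflated matrix must remain positive definite,
  otherwise the request is rejected.
* **Spatial field** — the ICAR law conditioned on one area fixed at
  zero is a proper Gaussian whose precision is the corresponding
  principal submatrix of Q; a draw is obtained by dense Cholesky solve,
  recentred to sum to zero, and rescaled to the requested empirical
  marginal sd. This is equivalent in law (up to the imposed scaling) to
  sampling the non-null eigenvector directions, and much cheaper.
* **Covariate effects** — linear slopes, or an inverted-U
  `−c (x − m)²`. The self-harm rurality default (`c = 0.054`,
  `m = −0.14`) is back-solved from the published percentile relative
  risks of the rurality curve (0.953/1.076/0.907 at the 5th/50th/95th
  percentiles), i.e. the suburban-excess shape.
* **Censoring** — optional disclosure flags on counts ≤ 5, mirroring
  release rules for small-area health data. Flags are metadata only;
  the fitting API refuses censored rows, and the orchestration layer
  drops them (with the induced sub-lattice) before fitting. How
  suppressed counts entered the original analyses is not documented
  anywhere we know of; drop-before-fit is this package's explicit
  policy.

What the generator does **not** emulate: real English contiguity (it
uses regular grid lattices; the graph-file interface accepts arbitrary
adjacency), age structure within areas (a single rate band by default),
repeat-admission mechanics, skewed score distributions (scores are
Gaussian, whereas real rurality scores have a long rural tail), or
multi-factor indicator panels. Passing tests therefore demonstrate
correctness of the machinery and calibration under these idealised
conditions, not epidemiological conclusions about real data.

## Numerical and design choices

* Interior spline knots follow the percentile placement; for skewed
  scores percentile and equal-spacing prescriptions disagree, and
  percentile placement is taken as operational.
* RW1 smooths discretize the score into 100 equal-width bins by default
  (configurable): fine enough to look smooth, coarse enough that most
  bins are populated at n ≥ 2,000.
* Percentiles of score distributions use the nearest-rank
  (inverted-CDF) empirical definition; printed tables round at display
  only, and high/low RR ratios are always computed from unrounded
  values.
* Decile and category splits spread any remainder deterministically
  (largest deciles last, remainder areas in the lowest SHR categories),
  with ties broken by stable area order, so margins are reproducible.
* Degenerate inputs fail loudly: islands (areas with no neighbours) are
  rejected because the ICAR conditional mean is undefined for them;
  constant indicator columns, all-zero rate schedules, non-finite
  predictors and non-positive-definite correlation targets all raise.

## Problem sizes

Test and acceptance runs are sized for a single desk core: oracle and
coverage checks on 2,000-area lattices, DIC spatial-vs-none
discrimination on 400 areas, spline-vs-linear discrimination on
1,600 areas (chosen so the expected deviance gain from the inverted-U
effect, which grows with n, sits well above the DIC decision threshold
of 3), and generator calibration at the study-scale 6,781. Replicate
properties (coverage, DIC win rates) are framed as majorities over 20
(or 10) independent replicates rather than point matches, since DIC
values carry Monte-Carlo and sampling error.

## Known limitations

* The ICAR spatial-dependence strength is not estimated (no proper-CAR
  or Leroux parameter); dependence is all-or-nothing given τ_s.
* Single-site Metropolis mixes slowly for very strong fields on large
  lattices; the effective sample size diagnostics should be checked
  when pushing beyond ~5,000 areas.
* The two outcomes are modelled independently; shared-component joint
  models are out of scope (cross-outcome overlap is assessed
  descriptively via decile cross-tabulation and correlation of fitted
  risks).
* `EffectCurve` evaluation clamps outside the training score range
  (constant extrapolation).
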