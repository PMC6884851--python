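# Methods

## Model

For child `i` with birth weight `y_i` (kg), categorical covariate vector
`w_i`, metrical covariates `x_i1` (mother age, years) and `x_i2`
(antenatal visits, count), and district `d_i`, the conditional
`τ`-quantile is modelled additively:

    q(τ | x_i) = w_i' γ_τ + f_1,τ(x_i1) + f_2,τ(x_i2) + f_spat,τ(d_i)

`spatqreg` fits this at extreme levels (defaults τ = 0.05 and 0.95, the
low/high birth-weight tails; τ = 0.5 reduces to median regression,
the analogue of ordinary mean regression for symmetric noise).

**Priors.**

* Fixed effects `γ_τ`: independent zero-mean Gaussians with precision
  `1e-6` — a proper but effectively flat realization of a diffuse
  prior.  Dummy (treatment) coding against declared reference levels,
  intercept first, so coefficients are per-level contrasts in kg.
* Each smooth `f_j`: an intrinsic GMRF on the sorted unique covariate
  values, density `p(f | δ) ∝ δ^{(n-m)/2} exp(-δ/2 f'Qf)`.  The default
  is a second-order random walk (`Q = D₂'D₂`, rank deficiency `m = 2`),
  which penalizes curvature only — a locally quadratic smoother; a
  first-order walk (`m = 1`, locally constant/linear) is available per
  term.  Ties share one latent value.
* District effect: intrinsic CAR on the adjacency graph,
  `Q = diag(n_i) − A`, `m` = number of connected components.  The
  implied full conditional of district `i` is Normal with mean the
  average of its neighbours' effects and precision `δ·n_i`.  Only the
  structured effect is modelled; no unstructured i.i.d. district
  component is added.
* Block precisions `δ`: Gamma(shape 1, rate 5·10⁻⁵) by default — a
  diffuse standard in the GMRF literature — configurable per block.

**Identifiability.** Every intrinsic block (smooths, spatial) carries
an exact sum-to-zero constraint; the intercept lives with the fixed
effects.  The constraint is imposed by conditioning by kriging after
each block draw — `x* = x − P⁻¹1 (1'x)/(1'P⁻¹1)` — which is exact
conditioning of the Gaussian full conditional, not a soft penalty.
Retained draws satisfy `|Σf| < 1e-8`.  For RW2 blocks only the sum is
constrained: the linear component of the smooth remains and is
informed by the data (it is exchangeable with a linear fixed effect;
constraining it too would change the model, not just the
parameterization).

## Inference

The working likelihood is the asymmetric Laplace distribution,
`log p(y) = log[τ(1−τ)/σ] − ρ_τ((y−μ)/σ)` with the check loss
`ρ_τ(u) = u(τ − 1{u<0})`; it places mass exactly τ below its location,
so a posterior over μ is a posterior over the conditional τ-quantile.
Its normal–exponential mixture — `y = μ + θv + κ√(σv) z`,
`v ~ Exp(rate 1/σ)`, `θ = (1−2τ)/(τ(1−τ))`, `κ² = 2/(τ(1−τ))` — makes
every regression block conditionally Gaussian.  One Gibbs cycle:

1. `1/v_i ~ InverseGaussian(√(ψ/χ_i), ψ)` with `χ_i = (y_i−μ_i)²/(κ²σ)`
   and `ψ = 1/(2τ(1−τ)σ)` (the GIG full conditional of `v_i` at index
   ½, drawn through its reciprocal).
2. Each Gaussian block from its multivariate-normal full conditional:
   precision = block prior precision (`δQ`, or the diffuse diagonal for
   the fixed block) plus the `ω`-weighted design cross-product, where
   `ω_i = 1/(κ²σv_i)`; pseudo-response `y_i − θv_i`.  Dense Cholesky
   solves — every block here is small (≤ a few dozen fixed columns,
   ≤ 35 grid values, ≤ 28 districts), so sparse machinery would buy
   nothing.
3. `δ_block ~ Gamma(a + (n−m)/2, b + f'Qf/2)` — the shape uses the
   structure matrix rank `n−m`, consistent with the prior's
   generalized-determinant exponent `(n−m)/2`.
4. ALD scale: by default `1/σ` gets a Gamma(1, 1) prior and a conjugate
   update (`1/σ ~ Gamma(a + 3n/2, b + Σ(y−μ−θv)²/(2κ²v) + Σv)`).

**Why σ is sampled by default.** σ is a nuisance of the working
likelihood, and fixing it is common; but its value sets the sharpness
of the pseudo-likelihood.  On kilogram-scale data (residual spread
≈ 0.5 kg) a fixed σ = 1 makes the likelihood far flatter than the data,
and the accumulated posterior skew of ~100 effect parameters pushes the
posterior-mean quantile surface visibly outward at extreme τ (measured
in-sample mass below the τ = 0.05 surface drops to ≈ 0.03 at n = 2000).
Sampling σ lets the working likelihood adapt (posterior σ ≈ 0.04 on
such data) and restores calibration (≈ 0.045).  `sample_sigma=False`
reproduces the fixed-scale variant.

**Chain settings.** Defaults are 12,000 iterations, 2,000 burn-in,
thinning 5, seed mandatory; identical seeds give bit-identical chains
(a single `numpy` Generator drives every update in a fixed order).
The test suite and the acceptance script use shorter chains
(≈ 1,500–6,000 iterations at n = 300–5,000) — at these block sizes the
sampler mixes quickly and those lengths already reproduce the LP
check-loss minimizer to < 0.03 per coefficient; they are the package's
standard problem sizes for verification runs.

**Numerical details.** `χ_i` is floored at 1e-12 (a residual of exactly
zero would make the GIG draw degenerate); Cholesky factorization
retries once with a trace-scaled 1e-10 jitter; a non-finite full
conditional aborts with the block name and iteration.  The GMRF
eigendecompositions use a relative eigenvalue threshold of 1e-9 to
separate the null space.

## Model summaries

* `posterior_summary`: per coefficient mean, sd, equal-tailed 95% CI
  and a significance flag (CI excludes 0).  Hyperparameters are
  reported as posterior means of `1/δ` per block — a block "variance
  parameter" is inherently ambiguous (prior precision vs effect
  variance), so the reported quantity is named explicitly.
* `spatial_effect_table`: per district posterior mean, 95% CI and a
  three-way class (negative / insignificant / positive) by the CI's
  sign — the tabular form of a credible-interval map.
* DIC: `Dbar + pD` with the deviance `−2Σ log ALD(y_i; μ_i, σ, τ)`
  averaged over retained draws and `pD = Dbar − D(θ̄)` at
  posterior-mean parameters.  DIC values are comparable across model
  structures *at the same τ* only; across τ the working likelihoods
  differ.

## Screening

Birth weight is categorized (< 2.5 kg low, 2.5–4.5 kg inclusive normal,
> 4.5 kg high) and cross-tabulated against each categorical covariate
with a Pearson chi-square test (no continuity correction — the tables
are multi-level).  Bivariate screening fits one single-term frequentist
quantile regression per candidate (statsmodels `QuantReg`) and retains
a covariate when any level coefficient (or the metrical slope) has
p < 0.20; the permissive 20% gate deliberately lets marginal candidates
into the multivariable model.  Standard errors use the kernel sparsity
estimate of the minimizer's asymptotic variance.  Screening is per-τ:
the retained set may differ between tails.  Under a null covariate the
gate fires at ≈ 17–20% — slightly conservative because the sparsity
estimate is itself noisy at moderate n.

## Synthetic data generator

The generator emulates the structure of a DHS-style extract, not any
real population: ~28 districts on a 4×7 rook grid (ring graphs
available), mother age discrete uniform 15–49, antenatal visits
Poisson(3.5) capped at 15, and category frequencies of survey-like
magnitude (wealth quintiles 20% each, smoking 3%, education mostly
primary).  Birth weight is built from the additive model itself:
intercept 3.1 kg, per-level fixed effects of 0.05–0.25 kg, centred
smooth effects of ±0.15 kg, and an ICAR district effect drawn at
precision `δ_spatial = 4` (district shifts of a few tenths of a kg).

Two noise modes serve two purposes:

* **ald** — ALD(0, σ, τ) noise with σ chosen so the residual sd is
  0.5 kg at the stated τ: the linear predictor *is* the true
  τ-quantile, giving exact ground truth for sampler calibration and
  CI-coverage checks.
* **gaussian** — heteroscedastic normal noise, log σ linear in wealth
  (offsets +0.25 … −0.25 around σ₀ = 0.4 kg) with a zero mean effect of
  wealth.  The true tail coefficients of wealth then flip sign between
  τ = 0.05 and 0.95 — the opposite-tail phenomenon that motivates
  quantile regression — and no fitted model is exactly "true",
  exercising the method under realistic misspecification.

What the generator does **not** emulate: survey design (clusters,
strata, weights — inference here is model-based and unweighted),
reporting heaping of birth weights, informative missingness (the
`missing_rate` option knocks values out completely at random), or a
real district map.  Passing recovery tests on these data therefore
demonstrates correctness of the algorithms, not fidelity of any
substantive conclusion about a real population.

## Data conventions

Rows with missing, non-finite or non-positive birth weight are dropped
and counted; rows with missing covariates are kept — a missing
categorical becomes an explicit `"missing"` level (never the
reference), and a record missing a metrical covariate simply
contributes no term from that smooth.  Adjacency input is a plain
neighbour list or GAL; asymmetric lists are symmetrized with a warning,
self-loops and unknown labels are errors, and isolated districts are
rejected at ICAR construction rather than silently given an
exchangeable prior.

## Known limitations

* The ALD device is a working likelihood: credible intervals are
  well-calibrated in the regimes tested (n ≥ ~2000, moderate p) but
  carry no general exactness guarantee, and agreement with other
  approximations (e.g. nested Laplace) is expected only to within
  estimator differences.
* Quantile surfaces are fitted per τ; nothing prevents crossing between
  separately fitted levels.
* DIC under a working likelihood is a relative, not absolute, measure
  of fit.
* The marginal log-likelihood is not computed.
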