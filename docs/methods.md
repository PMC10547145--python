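# Methods

## The problem

Extended-family studies let one split the variance of a quantitative trait
into an additive genetic part, transmitted through the pedigree, and a
residual environmental part.  The classical polygenic model makes two
strong implicit assumptions about the genetic part: its variance is the
same for everyone, and the genetic effects expressed by two relatives are
perfectly correlated (apart from the kinship weighting).  When genetic
effects depend on an environment — years of education, an income score,
any continuous exposure — both assumptions fail, and that failure *is*
genotype-by-environment interaction (GxE).  famgxe implements a mixed
model in which the additive genetic variance and the genetic correlation
are smooth functions of a continuous environment, together with the
testing protocol needed to decide, per trait×environment dyad, whether
either function deviates from the polygenic baseline.

## Models

### Polygenic baseline

For a phenotype vector y of n related individuals,

    y = Xβ + g + e,    Cov(y) = Σ = K σg² + I σe²,

where K = 2Φ is the additive relationship matrix computed from the
pedigree by the standard tabular recursion (Φ the kinship matrix; a
non-inbred individual has K_ii = 1, an inbred one 1 + F).  Heritability is
h² = σg²/(σg² + σe²).  Fitting is full maximum likelihood: β is profiled
out by GLS at every covariance evaluation, and because the total variance
σp² = σg² + σe² can also be profiled in closed form, the likelihood
reduces to one dimension in h².  We maximize it on [0, 1] with a coarse
grid bracketing a bounded scalar search, always evaluating the σg² = 0
boundary as a candidate; this cannot miss a boundary solution and has no
convergence tuning to speak of.  SE(h²) comes from the delta method on
the numerically estimated observed information of (log σg², log σe²);
boundary estimates carry `nan` SE (reported as "unreliable") because the
quadratic approximation fails there.

### Interaction model

The environment index q enters through three log-linear functions
(q̄ is the analysis-sample mean of q):

    σg²(q)     = exp(αg + γg (q − q̄))         genetic variance
    ρg(qi,qj)  = exp(−λg |qi − qj|)            genetic correlation, λg ≥ 0
    σe²(q)     = exp(αe + γe (q − q̄))         residual variance

giving the phenotypic covariance

    Σ = K ⊙ Ψ + Δ,
    ψij = exp(αg + ½γg(qi + qj − 2q̄) − λg|qi − qj|),
    Δ   = diag(exp(αe + γe(qi − q̄))).

Σ is positive definite for every valid parameter set: exp(−λ|·|) is a
valid (exponential/Ornstein–Uhlenbeck) correlation in one dimension, the
outer variance scaling preserves positive semidefiniteness, the Schur
product with PSD K stays PSD, and Δ adds a strictly positive diagonal.
Setting γg = λg = γe = 0 recovers the polygenic model with
σg² = exp(αg), σe² = exp(αe); the exponential re-parameterization keeps
the variance components positive without explicit constraints.

The residual side is variance-only (Δ diagonal): no residual correlation
function is modeled.

For a two-environment contrast the summary interaction variance is
σ²gΔ = σg1² + σg2² − 2 ρg σg1 σg2, which is 2σg²(1 − ρg) at equal
variances and zero iff the variances are equal and ρg = 1.  Only this
summary formula is provided; discrete two-environment fitting is out of
scope.

### BLUP environment correction

Environment indices like education are themselves heritable, so a naive
GxE test partly contrasts genotypes with their own genetic propensity for
the environment.  We therefore fit the polygenic model to q itself,
predict each individual's additive genetic value by BLUP,
ĝ = σ̂g² K Σ̂⁻¹ (q − Xβ̂) (identical to the genetic-effect solution of
Henderson's mixed-model equations, verified by test), and analyze
q_corrected = q − ĝ.  The fixed-effect design for q is intercept-only and
the corrected index is not re-standardized, so γ and λ stay in
interpretable per-environment-unit terms.  The β̂ used is the GLS estimate
from q's own polygenic fit.

## Fitting and numerics

* **Block structure.**  Families are mutually unrelated, so K — and with
  it every model covariance — is block-diagonal after grouping by family.
  All fitters detect the blocks from the nonzero pattern of K (connected
  components) and factor per family, which makes a likelihood evaluation
  on ~1,100 individuals a matter of ~40 small Cholesky factorizations.
  The public `polygenic_loglik`/`gxe_loglik` functions evaluate the same
  density densely and are held to 1e−8 agreement with a generic
  multivariate-normal oracle.
* **Optimization.**  The interaction model is maximized by L-BFGS-B over
  the free members of (αg, γg, λg, αe, γe) with β profiled by GLS,
  warm-started from the polygenic fit (αg = ln σ̂g², αe = ln σ̂e², slopes
  zero).  λg is bounded in [0, 50/range(q)] — correlations below e⁻⁵⁰
  are numerically zero and larger rates create plateaus; the same scaled
  bound (±50/range(q)) guards the γ slopes against overflow.
* **Boundary handling.**  Whenever λg is free, the λg = 0 sub-model is
  fitted first (recursively, through the same code path) and serves both
  as a second start and as a candidate solution adopted outright when the
  boundary attains the maximum (within 1e−8).  Consequences: nested
  log-likelihoods are exactly monotone, and the λg likelihood-ratio
  statistic is exactly zero — not merely tiny — when the boundary wins,
  which is what gives the boundary test its clean point mass at 0.
* **Standard errors.**  From the numerically estimated observed
  information (central-difference Hessian) of the free parameters.  At a
  λg = 0 solution the Hessian is evaluated through the smooth extension
  of the likelihood (the correlation kernel is evaluable marginally past
  zero and the covariance stays positive definite for the small stencil
  steps), which matches the common variance-components practice of
  reporting information-based SEs at boundary solutions; if the stencil
  nevertheless leaves the positive-definite region, the parameter is
  excluded and reported with `nan` SE.
* **Degenerate inputs.**  K = I makes (σg², σe²) identifiable only as a
  sum — flagged with a warning.  A zero-range environment makes λg
  unidentifiable — it is forcibly constrained with a warning.  A negative
  LRT beyond 1e−6 (independent optimizations of nested models) triggers a
  refit warning; within 1e−6 it is clamped to zero.

## Preprocessing

Traits are regressed on [1, age, sex, age², sex·age, sex·age²] by OLS
(age mean-centered first — affects coefficients, not residuals; aliased
columns of single-sex samples dropped with a warning) and the residuals
are mapped to normal scores by the Blom variant of the rank-based
inverse-normal transform, Φ⁻¹((r − 3/8)/(n + ¼)), with average ranks for
ties.  The mixed models then carry an intercept-only design.  The Blom
offset and average-rank tie rule are deterministic, symmetric choices
among the standard variants.  Environment indices are used on their raw
(BLUP-corrected) scale, not residualized or transformed.

## Inference

The likelihood-ratio statistic Λ = −2(lnL_null − lnL_alt) is referred to
mixture-χ² distributions because the tested parameters can sit on the
boundary of the parameter space under the null:

| test | null | reference |
|---|---|---|
| stage 1: interaction vs. polygenic | γg = λg = γe = 0 | ½χ²(2) + ½χ²(3) |
| variance heterogeneity | γg = 0 | χ²(1) |
| genetic correlation | λg = 0 | ½·(point mass at 0) + ½χ²(1) |
| residual heterogeneity | γe = 0 | χ²(1) |

The two-stage protocol: (1) test the full interaction model against the
polygenic model; (2) test each interaction parameter singly.  A parameter
is dropped into a reduced model only when its SE exceeds its |MLE| *and*
its formal single-parameter test is non-significant at α = 0.05 (an
unavailable SE counts as exceeding); remaining tests are then rerun
against the reduced alternative, with every null re-optimizing all
remaining free parameters.  α = 0.05 is a package choice for the
screening rule's "non-significant".  P-values are reported to four
significant figures, scientific notation below 1e−3.  No multiplicity
correction is applied across dyads.

## Synthetic data

The generator emulates the target study design: by default 42 independent
three-generation families (one founder couple; each couple's offspring
count is truncated Poisson with mean 4.0 on 0..8; every child marries an
unrelated in-marrying founder), totalling ≈1,050–1,150 individuals.  The
offspring mean was set so that 42 families land at the design's stated
cohort size.  The environment is simulated as q = mean + g + e with
g ~ MVN(0, K·h²·sd²) per family and independent residuals; defaults
(mean 10.16, SD 3.92, h² = 0.41) are education-like.  Phenotypes are
drawn exactly from Σ = K ⊙ Ψ + Δ at the configured parameters via
per-family Cholesky, with modest age/sex fixed effects attached (age ~
U(16, 80), β_age = 0.02, β_sex = 0.25, β_age² = −4e−4) so that the
covariate machinery is exercised.  All generators are pure functions of
(config, seed).

What the generator does *not* emulate: ascertainment through probands,
informative missingness (only complete tables or MCAR drops), categorical
income ladders (environments are continuous), household/shared-
environment variance components, and real family-size distributions
(unpublished; the defaults are plausible stand-ins and fully
configurable).  Passing simulation tests therefore demonstrate
correctness of the estimator against its own generating process and
calibration of the tests under the design assumptions — not robustness
to those real-data features.

### Simulation studies

`run_simulation_study` repeats generate → (optionally BLUP-correct) →
fit → test and summarizes bias, 2·SE coverage and rejection rates.  Two
deliberate choices:

* Recovery and calibration studies fit the **raw** simulated trait with
  the age/sex design profiled in-model rather than running the
  inverse-normal pipeline: the rank transform rescales the trait, so
  variance-level parameters would not be comparable to the generating
  values.  The preprocessing path is exercised separately.
* Recovery studies skip the BLUP correction, because the phenotype is
  generated against the environment the fitter must see; correcting
  would shrink the index and inflate the slope estimates.  The
  correction's effectiveness (heritability of the corrected index
  dropping from 0.41 to below 0.2) is its own check.

Problem sizes used by the test suite: parameter recovery at the full
design (42 families, ≈1,100 individuals, 50 replicates); null
calibration at 15 families (≈400 individuals, 500 replicates), a size at
which the asymptotic mixtures are already accurate; kinship validated
against gene-dropping Monte Carlo with 10⁵ loci on a 20-member pedigree
containing an inbred (half-sib mating) loop.

## Known limitations

* Full ML, not REML: variance components carry the usual O(p/n) downward
  fixed-effect bias; with intercept-only or low-dimensional designs this
  is negligible at the target sample sizes.
* Wald (MLE ± 2·SE) intervals for λg are anti-conservative when the true
  decay rate is small: the sampling distribution piles up near the
  boundary where the local curvature is high, so information-based SEs
  understate the spread.  The likelihood-ratio test with the point-mass
  mixture does not suffer from this and is the inferential path the
  protocol actually uses.
* The 50:50 point mass of the λg boundary test is an asymptotic result.
  In small samples the boundary attracts more than half the mass (ML
  estimation of the nuisance parameters biases the boundary score
  negative), so the test is mildly conservative there; the calibration
  test in the suite measures this directly at a reduced cohort size.
* The genetic correlation function is a one-parameter exponential decay;
  crossing interactions that change sign cannot be represented.
* Genotype-by-sex interaction, marker-based (genomic) relationship
  matrices, X-linked kinship and multi-trait models are out of scope.
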