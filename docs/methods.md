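# Methods

## Model

At a diallelic X-linked SNP in *n* unrelated females, genotypes dd / Dd / DD
(D the designated risk allele) carry genotypic values {0, γ, 2} with
γ ∈ [0, 2] the degree of XCI skewness.  With the carrier indicator
X1 = I{Dd or DD} and the homozygote indicator X2 = I{DD}, the genotypic
value is γX1 + (2−γ)X2 and the working model is the GLM

    h(E[Y | G, Z]) = β₀ + β₁ X1 + β₂ X2 + bᵀZ,   β₁ = βγ,  β₂ = β(2−γ)

with logit link for binary traits and identity link for quantitative
traits, so γ = β₁/β with β = (β₁+β₂)/2.  The quantitative generative model
allows genotype-specific residual variances (σ₀², σ₁², σ₂²), motivated by
the inflated trait variance observed in heterozygous females; the
frequentist working fit deliberately ignores this heteroscedasticity (plain
OLS), which is a documented model/data mismatch shared by the estimators it
reproduces.

The risk allele must be named explicitly.  A minor-allele default would be
wrong in general — in the shipped worked example the risk allele is the
*major* allele (frequency 0.57), and flipping alleles maps γ to 2−γ.

## Frequentist estimators

**Fitting.**  Logistic fits use iteratively reweighted least squares to a
relative log-likelihood tolerance of 1e-10 (max 100 iterations; separation
is reported via a `converged` flag rather than raised).  The coefficient
covariance is the inverse *empirical* (outer-product-of-scores) Fisher
information Σᵢ(Yᵢ−p̂ᵢ)²xᵢxᵢᵀ; a `cov_type="observed"` switch provides the
model-based observed information for sensitivity analysis.  On saturated
3-cell grouped data the two coincide exactly (cellwise, a·b²/(a+b)² +
b·a²/(a+b)² = ab/(a+b) = n·p̂(1−p̂)).  Quantitative fits are OLS with the
dispersion-estimated covariance σ̂²(DᵀD)⁻¹, σ̂² = RSS/(n−p).  When
covariates are present the (β₁, β₂) block is obtained by marginalizing the
full inverse information.  The triple consumed downstream is v₁ = Var β̂₁,
v₂ = Var β̂ = (Varβ̂₁+Varβ̂₂+2Cov)/4, v₁₂ = Cov(β̂₁, β̂) = (Varβ̂₁+Cov)/2.

**Fieller.**  Inverting the Wald test of γ = γ₀ gives the quadratic
Aγ₀² + Bγ₀ + C ≤ 0 with A = β̂²−z²v₂, B = 2(z²v₁₂−β̂₁β̂), C = β̂₁²−z²v₁.
The case analysis (A>0: interval; A<0, Δ>0: complement of an interval;
A<0, Δ<0: whole line; A=0 or Δ=0: empty by convention) is applied before
intersecting with [0, 2].  Numerical choices:

* roots are sorted, since (−B±√Δ)/(2A) reverses order when A < 0;
* analytic roots are open endpoints; the truncation boundaries 0 and 2 are
  closed (printed style `[0, 1.6579)`);
* z is the standard-normal quantile (large-sample theory; no t-correction
  even at small n);
* the measure-zero tangency Δ = 0 is mapped to the empty set, following the
  construction literally rather than returning the single root;
* β̂₁ = β̂₂ = 0 exactly leaves the ratio undefined: NaN plus a flag, never an
  arbitrary value.

The whole case analysis is tested against brute-force grid inversion of the
Wald test on 201 γ₀ points for 10⁴ random coefficient/covariance draws.

**Penalized Fieller.**  The penalized log-likelihood
pl(β) = −(β̂−β)²/(2v̂₂) + λ log|β| has maximizer
β* = β̂/2 + sign(β̂)√(β̂²/4+λv̂₂); the numerator is bias-corrected as
β₁* = β̂₁ + γ̃(β*−β̂), γ̃ = β̂₁/β*, and first-order Taylor variances (the
O(n⁻³) remainders are dropped) give v₂* = ω²v̂₂,
v₁* = ω⁻²v̂₁ − 4(ω⁻¹−1)γ̃v̂₁₂ + 4(1−ω)²γ̃²v̂₂,
v₁₂* = v̂₁₂ − 2ω(1−ω)γ̃v̂₂ with ω = β*/(2β*−β̂).  The interval is the same
quadratic construction on the starred quantities.  Choices:

* λ defaults to z²₁₋α/₂/4 (≈ 0.9604 at α = 0.05), the smallest penalty that
  guarantees a bounded interval; larger λ shrinks width and coverage toward 0;
* the same λ is used for the point estimate and the interval, keeping the
  two mutually consistent (the construction leaves this open);
* sign(0) := +1, so β̂ = 0 still yields β* = +√(λv̂₂) and the estimator is
  defined everywhere;
* the starred quantities are computed in one pass (γ̃ from the unadjusted
  β̂₁), exactly as the printed formulas read.

A consequence asserted in tests: γ̂_PF = 0 exactly when γ̂_F = 0, because
sign(β₁*/β*) = sign(β̂₁β̂).

## Bayesian estimators

Likelihood as above, parameterized directly in (β₀, β, γ, b) and, for
quantitative traits, (σ₀, σ₁, σ₂).  Independent priors:

| parameter | prior | default |
|-----------|-------|---------|
| γ | U(0, 2) ("BU") or N(1, 1) truncated to [0, 2] ("BN") | — |
| β₀, β | Normal | N(0, 10²) |
| b_m | Normal (diagonal) | N(0, 10²) |
| σⱼ | Exponential | rate 1 |

The BN prior encodes that random inactivation (γ = 1) is the most common
state while keeping appreciable mass near the boundaries; BU is the
noninformative reference.  At β = 0 the likelihood carries no information
about γ (it drops out); the prior keeps the posterior proper and no special
handling is applied.

**Sampler.**  Hamiltonian Monte Carlo with analytic gradients on an
unconstrained scale: γ = 2·sigmoid(η) and σⱼ = exp(τⱼ), Jacobians included.
Under both priors the boundary values γ ∈ {0, 2} have zero posterior mass
only in the limit; draws are returned on the constrained scale.  One master
seed fans out per-chain seeds through `numpy.random.SeedSequence`.
Implementation choices:

* jittered leapfrog trajectory length, L ~ Uniform{1..20}, which avoids
  periodicity without trajectory-level adaptation;
* dual-averaging step-size adaptation towards a 0.99 target acceptance rate
  during warmup (γ = 0.05, t₀ = 10, κ = 0.75);
* a diagonal mass matrix estimated from the second warmup quarter, after
  which step-size adaptation restarts;
* proposals with energy error above 1000 after warmup are counted as
  divergences;
* duplicate (X1, X2, Y, Z) rows of qualitative data are collapsed to
  weighted patterns (at most six for grouped case-control input), so the
  full sampling profile is cheap even for cohorts of thousands.

Defaults are 8 chains × 20,000 iterations with the first half discarded as
warmup (80,000 retained draws); `SamplerConfig.reduced()` is the 4 × 2,000
profile used inside replicate studies.  Split-chain R̂ is computed for every
parameter; R̂ ≥ 1.05 emits a warning, not an error.

**Summaries.**  The point estimate is the mode of the γ draws from a binned
kernel density estimate: draws are histogrammed on a 2,001-point grid over
[0, 2] and smoothed with a Gaussian kernel of Silverman bandwidth using
reflecting boundaries, which removes the KDE boundary bias at 0 and 2; the
argmax is the mode.  This estimator is deterministic given the draws and
cheap; it is one of several defensible mode definitions, and comparisons
with externally reported modes should allow for the dialect.  The credible
interval is the HPDI: the shortest contiguous window of sorted draws
containing ⌈level·S⌉ of them, with sample values as endpoints (verified
against exhaustive window enumeration).  HPDIs are single intervals inside
[0, 2] by construction — the Bayesian methods cannot produce extreme point
estimates, noninformative sets, empty sets or discontinuous intervals.

## Simulation designs

Genotype frequencies (g₀, g₁, g₂) = (q²+ρpq, 2(1−ρ)pq, p²+ρpq); invalid
(p, ρ) combinations producing negative frequencies are rejected.

*Qualitative*: the DD-vs-dd odds ratio is fixed at λ₂ = 2, so β = ln(λ₂)/2
and λ₁ = λ₂^(γ/2); case genotype probabilities are cⱼ ∝ (g₀, g₁λ₁, g₂λ₂)
with exp(β₀) the normalizer; n/2 cases and n/2 controls are drawn as
trinomials (per-group trinomial sampling, equivalent in distribution to
per-subject draws).  Setting λ₂ = 1 gives the null model c = g.

*Quantitative*: genotype counts are one trinomial of size n; traits are
normal with means β₀ + βγX1 + β(2−γ)X2 (β₀ = 0, β = 0.3) and
genotype-specific variances (1, 1.2, 1) or (4, 4.8, 4).

Replicate studies default to 500 replicates with γ drawn once per replicate
from U(0, 2) and stored with the results.  Reference scenario values used in
the test suite (qualitative, n = 500, MAF 0.3, ρ = 0): Fieller MSE ≈ 0.29,
~25–27% extreme estimates, ~30% noninformative intervals, coverage inside
the binomial band 93.05–96.95%.  Bayesian replicate rows are checked at a
scaled-down design — 50 replicates with the reduced sampler profile and
correspondingly widened bands — because 500 × 80,000-draw runs are beyond
desk scale; this is a package design choice, and the full profile remains
available via `SamplerConfig()`.  Covariate-bearing simulation scenarios are
supported through a user-supplied covariate generator hook rather than a
built-in design.

## What the generator does and does not emulate

The synthetic designs cover: departure from Hardy–Weinberg equilibrium in
females (ρ ≠ 0), low and moderate allele frequencies, balanced case-control
sampling, and heteroscedasticity across genotypes for quantitative traits.
They do not cover: family or population structure, genotyping error or
missingness, linkage disequilibrium between SNPs, covariate confounding
(beyond the hook), non-normal quantitative traits, or non-additive genetic
models — under over/underdominance the true heterozygote value lies outside
[0, 2] and is not identifiable as XCI skewness from mean effects alone.
Passing tests therefore demonstrate correctness of the estimators under the
stated generative models, not robustness to these real-data features.

## Degenerate inputs and edge cases

* Grouped counts are accepted only for qualitative traits without
  covariates; anything else requires individual-level rows.
* Rows with missing genotype or trait are dropped with a logged count; no
  imputation.
* Rank-deficient designs and zero residual degrees of freedom raise;
  logistic separation flags `converged=False` instead of raising so that
  replicate loops can record and continue.
* v₂ = 0 with λ > 0 is rejected in the penalized estimator.
* Empty replicate intervals are included in width statistics at width 0 by
  default (`drop_empty` excludes them); coverage of a discontinuous set
  means membership in either piece.

## Known limitations

* The HMC sampler is serial across chains; wall time for the full profile
  on grouped case-control data is tens of seconds, but large individual-level
  quantitative datasets scale linearly in n per gradient evaluation.
* The KDE mode and the HPDI assume an (approximately) unimodal marginal
  posterior; all observed γ marginals are unimodal, and the HPDI is defined
  as a single contiguous interval by construction.
* The frequentist quantitative fit ignores the genotype-specific variances
  of the generative model (see above).
* Only single-SNP, female-only, unrelated-subject analyses are supported.
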