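# Methods

## Model

All analyses fit the weighted animal model

    y = Xb + Za + Wv + e,   a ~ N(0, A σ²ₐ),   e ~ N(0, E σ²ₑ),

where `y` holds trait deviations (cows) or daughter trait deviations
(bulls), `X` codes the overall mean, breed, and sex nested within breed
(reference-level dummy coding, first level absorbed in the mean, degenerate
single-level factors dropped so `X` stays full rank), `A` is the pedigree
numerator relationship matrix, and `W` the column-standardized genotype
matrix `(x − 2p)/√(2p(1−p))`. Allele frequencies are taken from the full
standardising population (reference plus validation animals). This has two
consequences: validation genotypes standardize identically to training
ones, and the reference-subset GRM is not exactly singular — a GRM built
from own-sample frequencies always is, because centring puts the ones
vector in its null space.

### Record weights

`E = diag(1/wᵢ)` scales the residual variance per record:

    bulls:  w = d(1−h²)/(4−h²)
    cows:   w = r(1−h²)/(1 + (r−1)t − r h²)

with `d` effective daughters, `r` own records, `h²` single-record
heritability, `t` repeatability. A cow with `r = 1` has `w = 1` by
construction, anchoring σ²ₑ to the single-record scale. Bulls with `d = 0`
carry infinite error variance and are dropped with a warning rather than
erroring. For valid parameters (`h² ≤ t ≤ 1`) the cow denominator is
positive except in the degenerate limit `h² = t = 1`, which errors.
Milk-composition deviations use the linearised ratio
`(FY_P/MY_P)[FY/FY_P − MY/MY_P]` on the fraction scale; the CLI leaves the
×100-to-percent rendering to the caller.

### Trait-parameter presets

Milk traits default to `h² = 0.33, t = 0.56`; stature `0.45`; fertility
`0.03/0.05`; survival `0.025/0.035`. All are overridable per analysis.

## GBLUP

The genomic model replaces `Wv` by `Qg`, `g ~ N(0, G σ²_g)`. `G` follows
the Yang et al. estimator: off-diagonals are mean standardized
cross-products; the diagonal uses `1 + (x² − (1+2p)x + 2p²)/(2p(1−p))`
averaged over markers, which estimates `1 + F`. A `plain` mode uses
`WW'/m` throughout; the back-solving identity `W v̂ = ĝ` with
`v̂ = W'G⁻¹ĝ/m` is exact in plain mode and approximate with the Yang
diagonal, so plain is the default wherever SNP effects are back-solved.
If a GRM is numerically singular its inversion adds a 1e-6 diagonal ridge
once, with a log message; the inverse is cached.

Variance components are estimated by REML. Models with a single random
term ({a,e} or {g,e}) use exact one-dimensional profiled REML: whiten by
`E^(−1/2)`, eigendecompose the whitened covariance structure once, then
each restricted-likelihood evaluation is O(n²) and the variance ratio is
maximised by bounded scalar search. The general {a,g,e} model uses
EM-REML (σ²ᵤ ← (û'K⁻¹û + tr(K⁻¹C_uu))/q; σ²ₑ ← y'E⁻¹ê/(n−p)), whose
iterates provably never decrease the restricted likelihood — a property
the test suite asserts directly. Both routes agree on their shared models
to <1 % (tested). Convergence: relative component change < 1e-6 or 200
iterations, with a flagged non-converged return rather than an exception.

The mixed-model equations are solved by dense Cholesky factorisation of
the blocked coefficient matrix, refusing systems beyond 20 000 equations
(this is a desk-scale tool). The three block fixed-point identities are
satisfied to solver precision (~1e-12 measured, asserted < 1e-8).

## BayesR

SNP effects follow a four-component normal mixture with variances
`(0, 10⁻⁴, 10⁻³, 10⁻²) · σ²ₐ₂`, where σ²ₐ₂ is the additive variance of a
genotype-free pedigree model estimated before the run (or supplied). Each
Gibbs iteration:

1. σ²ₑ ← ẽ'E⁻¹ẽ / χ²₍ₙ₋₂₎ — the conjugate scaled-inverse-χ² draw in the
   scale parameterisation (the literal mean of this draw is S/(df−2); the
   scale convention matches standard BayesR practice).
2. b ← N([X'R⁻¹X]⁻¹X'R⁻¹y*, [X'R⁻¹X]⁻¹), one joint block draw.
3. per-animal single-site polygenic update with conditional precision
   `Zᵢ'Rᵢᵢ⁻¹Zᵢ + Aᵢᵢ⁻¹σₐ⁻²` and mean
   `(Zᵢ'Rᵢᵢ⁻¹y*ᵢ − σₐ⁻² Σ_{j≠i} A⁻¹ᵢⱼ ãⱼ) / precision`, validated against
   the MME solution as the chain's long-run mean.
4. σ²ₐ ← ã'A⁻¹ã / χ²₍q₋₂₎ with q = number of polygenic effects.
5. per marker, in a fresh random permutation each iteration: component
   log-scores `L_k = −½ln(1 + cⱼσ²_k) + ½·rhs·v_{j,k} + ln pr_k` with
   `cⱼ = Wⱼ'R⁻¹Wⱼ`, `rhs = Wⱼ'R⁻¹y*` and `v_{j,k} = rhs/(cⱼ + σ_k⁻²)`
   (the component-constant `y*'R⁻¹y*` term cancels in the softmax and is
   dropped); a component is drawn by log-sum-exp softmax, then the effect
   from `N(v_{j,k}, (cⱼ + σ_k⁻²)⁻¹)`, exactly 0 for the null component.
6. pr ← Dirichlet(α + component counts), α = (1,1,1,1).

Residuals are maintained incrementally and recomputed from scratch every
1000 iterations to bound float drift (verified < 1e-8 after thousands of
iterations). Divergence (σ²ₑ exceeding 10⁶× the phenotypic variance)
aborts with diagnostics; note that at very small n (≲10 records) the
heavy-tailed χ² draws make benign excursions of that size possible.
Chains are seeded `base_seed + chain_index` and are bit-reproducible; the
final estimate averages per-chain posterior means. Defaults are 30 000
iterations, 20 000 burn-in, five chains, no thinning.

The marker and polygenic loops are numba-compiled (the genotype matrix is
held column-major); throughput is roughly 10⁷ marker×record updates per
second per core, i.e. ~9 s per 1000 iterations at n=1500, m=5000.

Oracle checks: with the mixture forced to one non-zero component and
frozen proportions the sampler is Bayesian ridge regression, and its
posterior-mean effects correlate >0.99 with the closed-form ridge solution
(n=300, m=500); the conjugate χ² and Dirichlet draws match their
analytical moments by Monte Carlo.

A practical identifiability note: a non-zero class with variance σ²_k is
distinguishable from the null only when `n·σ²_k/σ²ₑ` is appreciably above
zero. At small n with a realistic σ²ₐ₂ the 10⁻⁴ class is invisible and
markers diffuse between it and the null — the mixture proportions then
follow the prior rather than collapsing. Tests that assert null-collapse
therefore use a prior scale at which every class is detectable.

## Prediction and validation

SNP-only predictions are `ŷ_v = W_val v̂` (validation genotypes
standardized with training frequencies); total genetic merit adds the
polygenic solution. Accuracy is the Pearson correlation of prediction and
phenotype (or true genetic value in simulations); bias is the regression
slope of phenotype on prediction; the approximate standard error of an
accuracy is `1/√n` reported to 3 decimals. Validation is scored within
breed label, unweighted.

## QTL windows

Windows of 250 kb slide by 50 kb along each chromosome (0-based half-open
internally, 1-based bp in files); a chromosome shorter than one span gets
a single covering window. The "average window" for thresholds is the mean
variance over windows containing at least one marker, per trait (and per
breed when split). Thresholds use strict inequality: >50× the average
calls a QTL, >3× admits a trait into pleiotropy patterns. Merging chains
flagged windows whose successive midpoints are <0.5 Mb apart and whose
per-trait −/+/n patterns agree exactly. Region classes take the yield
trait with the largest variance ratio and suffix −/+/n from the sign of
its local-GEBV correlations with the other yield traits; regions whose
only supra-threshold trait is protein percentage are grouped with MYn.
Breed specificity is recorded when a region is flagged in exactly one
breed. Overlapping windows double-count marker effects by design; regions
resolve the redundancy.

A geometric caveat discovered in testing: a point QTL occupies ~5
overlapping windows, and those windows participate in the genome-wide
mean. On short test genomes (<~20 Mb at these settings) the mean is
dominated by the QTL's own windows and the 50× ratio becomes
unreachable; precision experiments therefore use a 60 Mb single
chromosome.

## Synthetic data generator

The generator emulates exactly the structure the estimators consume:

* **Genomes** — founder haplotypes with first-order Markov LD (adjacent
  allele copied with probability 0.7), 5 chromosomes, 50 kb marker
  spacing. Each of three breeds drifts independently for 30 generations
  through a 200-haplotype bottleneck pool with crossover probability
  0.001 per 50 kb interval per meiosis (the physically realistic order;
  larger values re-phase LD entirely and destroy across-breed signal).
* **Architecture** — mixture-distributed effects on the standardized
  scale; by default 20 markers planted in the 10⁻² class plus ~30/15
  expected in the small classes, σ²ₐ₂ = 1.
* **Records** — cows draw r ∈ {1..3} with error variance σ²ₑ/w(r); bull
  daughter deviations are simulated directly as genetic value plus noise
  of variance σ²ₑ/w(d), d ~ round(Gamma(2, 50)) — only the weight
  structure matters to the estimators, so daughters are not simulated
  individually. σ²ₑ is set from the realized genetic variance so a
  single-record cow has the target h² (0.33 by default). Breed means and
  a sex effect are injected with known values.
* **Design** — breeds A and B form the reference (1500 phenotyped
  animals by default) with 100 genotype-only hold-outs each; breed C
  (150 animals) never enters the reference, playing the across-breed
  validation role.
* **hidden_qtl mode** — causal markers are dropped from the analysis
  panel so prediction must work through LD tagging. This is what makes
  across-breed accuracy degrade realistically (≈0.5–0.6 vs ≈0.92–0.95
  within-breed); with causal variants genotyped, effects transfer across
  breeds almost perfectly and the comparison is uninformative. The
  mixture-recovery experiments keep causal markers in the panel, since
  they compare per-marker component assignments.
* **Planted-QTL mode** — one common marker near the genome midpoint gets
  a fixed standardized effect sized to explain 10 % of phenotypic
  variance, for the mapping-precision experiments.

What the generator does **not** emulate: genotyping error, imputation
error, realistic demographic history, selection, multi-trait genetic
correlations, or genotype-by-environment effects. Passing tests
demonstrate correctness of the estimators and the direction of the
multi-breed phenomena under this idealised model, not performance on real
cattle data.

## Experiment sizes

Library defaults follow the standard protocol (30 000/20 000/5 chains);
the replicated experiments and the acceptance script use sizes chosen to
make the full battery run in minutes on one core while keeping every
effect measured well above its Monte-Carlo noise: mixture recovery on the
default bundle with one 2500-iteration chain (1000 burn-in); twenty
planted-QTL replicates at n=500 records, m=1200 markers, 1200-iteration
chains; the breed comparison with one 2500-iteration chain. The
mapping-precision span comparison is evaluated at the 3× threshold
because the smeared GBLUP profile typically exceeds the 50× calling
threshold nowhere, which would make the comparison degenerate (the only
method that maps at all would lose it).

## Known limitations

* Dense linear algebra throughout: intended for ≲20 000 equations.
* EM-REML gives point estimates only; no standard errors on variance
  components are reported.
* The Yang-diagonal GRM breaks the exact back-solving identity; use plain
  mode when SNP effects are the target.
* Single-trait analyses only; pleiotropy is assessed through local-GEBV
  correlations across separately fitted traits, not a multi-trait model.
* The PLINK writer stores hard genotypes only; real-valued imputed
  dosages must use the TSV dialect.
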