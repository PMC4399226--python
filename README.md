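# dairygp

Multi-breed dairy genomic prediction and QTL mapping: a weighted **BayesR**
Gibbs sampler, a weighted **GBLUP** counterpart, and **local-GEBV
sliding-window QTL mapping** with nine-class pleiotropy labelling, exercised
end to end on a synthetic multi-breed population generator with known ground
truth.

## Who this is for

Quantitative geneticists who want a desk-scale, fully testable implementation
of the genomic-evaluation stack used in dairy cattle: phenotypes of unequal
precision (bull daughter trait deviations vs cow own records), a normal-mixture
prior on SNP effects for sharp QTL localisation, and window-variance QTL
mapping on the resulting marker solutions.

## The model

Phenotypes follow the animal model

```
y = Xb + Za + Wv + e,        e ~ N(0, E σ²ₑ),   E = diag(1/wᵢ)
```

with fixed effects `b` (mean, breed, sex within breed), pedigree polygenic
values `a ~ N(0, A σ²ₐ)`, and standardized SNP genotypes `W` (columns
`(x − 2p)/√(2p(1−p))`). Record weights follow the deregressed-proof forms

```
bulls: w = d(1−h²)/(4−h²)          cows: w = r(1−h²)/(1+(r−1)t − r·h²)
```

so a cow with one record has `w = 1` exactly.

**GBLUP** treats `Wv = Qg` with `g ~ N(0, G σ²_g)`, `G` the Yang et al.
genomic relationship matrix (a plain `WW'/m` mode is provided), estimates
variance components by REML, solves the three-block mixed-model equations,
and back-solves SNP effects `v̂ = W'G⁻¹ĝ/m`.

**BayesR** puts a four-component normal mixture on each SNP effect, with
variances `(0, 0.0001, 0.001, 0.01) · σ²ₐ₂` (`σ²ₐ₂` = pedigree additive
variance) and Dirichlet-updated proportions, sampled by Gibbs: error
variance, fixed effects, per-animal polygenic effects, polygenic variance,
per-marker component + effect, mixture proportions. Defaults follow the
standard protocol: 30 000 iterations, 20 000 burn-in, five replicate chains.

**QTL mapping** computes local GEBV `W_{j1:j2} v̂_{j1:j2}` in 250 kb windows
sliding by 50 kb; a window whose local-GEBV variance exceeds 50× the average
window contains a QTL; windows above 3× feed pairwise trait correlations;
nearby windows (midpoints < 0.5 Mb) with matching effect signs merge into
regions labelled FY/MY/PY × −/+/n.

## Worked example

```
dairygp simulate --seed 5 --markers 300 --scale 0.12 --outdir data
dairygp bayesr  --datadir data --outdir out \
    --iterations 300 --burn-in 100 --chains 1 --seed 1
dairygp predict  --datadir data --effects out/bayesr_effects.tsv --outdir out
dairygp validate --datadir data --predictions out/predictions.tsv \
    --out out/report.tsv
```

This small trial run prints:

```
mean markers per mixture class: 54.9 70.9 88.6 85.6
sigma2_e=0.3703
trait reference method breed  n  accuracy     bias  approx_se
   MY reference bayesr     C 18  0.543495 1.111261      0.236
```

The class counts are the average number of markers per mixture component
(null, then variances 10⁻⁴/10⁻³/10⁻² of the additive variance) in a
post-burn-in iteration; at this deliberately tiny scale the smallest
non-zero class is statistically indistinguishable from the null, so the
markers spread across components — at the default scale (5000 markers,
1500 reference animals) the null component absorbs >97 % of markers.
`sigma2_e` is the residual variance for a single cow record (phenotype
units²). The report row scores the phenotyped hold-out breed C: accuracy
`r(y, ŷ) = 0.54`, bias `b(y, ŷ) = 1.11` (1 = unbiased), approximate
standard error `1/√18 = 0.236`. `dairygp map-qtl` writes a BED-like region
table (0-based half-open coordinates) with variance ratios and the
pleiotropy class per region.

A full-scale library session (5000 markers, 1500 reference animals across
two breeds, a third breed held out) is shown in `dairygp.evaluation`; it
reproduces within-breed accuracy ≈ 0.92–0.94 against true genetic values
and a markedly lower across-breed accuracy ≈ 0.5–0.6, and localises a
planted QTL explaining 10 % of phenotypic variance to a ~500 kb
supra-threshold span where back-solved GBLUP effects smear it over tens of
Mb.

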