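# Methods

This note documents the models, numerical choices and limitations of the
package; it is the design record a maintainer should read before changing
defaults.

## Synthetic study generator (`simdata`)

**Genotypes.** Haploid 0/1 panels are generated by a hidden-Markov
haplotype-copying scheme: each arm has `n_founders` (default 8) founder
haplotypes; each line copies alleles from a founder and switches founders
between adjacent sites with probability 1 − exp(−d/`ld_block_bp`).  This
produces exponential-like r² decay with scale `ld_block_bp` (default
1,000 bp, the scale on which LD decays in wild *D. melanogaster*);
`ld_block_bp = 0` yields fully independent sites.  Sites are oversampled
and filtered so every realised MAF lies in `target_maf_range`
(default (0.05, 0.5], matching the common-variant analysis window).
Mean spacing is ~200 bp so 1-kb windows hold several SNPs at the default
scale.  Per-call DP ~ Poisson(40) and GQ ~ min(99, Poisson(60)), with a
`qc_fail_rate` sprinkling of low-DP/low-GQ calls so every QC branch is
exercised.

**Fitness.** Line genetic values are additive over randomly placed causal
sites — antagonistic causals contribute with opposite sign in the two
sexes, concordant causals with the same sign — and are then linearly
recoloured so the realised line-level (co)variance equals the target
**G** exactly (whiten by the empirical 2×2 covariance, colour by the
target).  This makes parameter-recovery tests sharp: estimator error is
attributable to the estimator, not to generator sampling noise.  Vial
observations add a block effect (σ²_block = 0.1) and sex-specific residual
noise.  Defaults (σ²_Gf = 0.27, σ²_Gm = 0.087, Cov = 0.023, σ²_R = 1)
target h²_f ≈ 0.42, h²_m ≈ 0.16, r_mf ≈ 0.15 — the magnitudes reported
for the real hemiclone panel.  Observable maps are kept affine — male
siring proportion ≈ 0.464 + 0.08·latent (0.464 being the empirical
wild-type share against the brown-eyed competitor), female eggs ≈
round(30 + 8·latent) — so that the Box-Cox → z-score funnel recovers the
latent scale; real assay nonlinearity (binomial sampling of progeny
counts, egg overdispersion) is deliberately not modelled, so passing
recovery tests demonstrate estimator correctness, not robustness to
distributional misspecification.

**Comparison panels.** Allele frequencies evolve by Wright-Fisher
binomial sampling (haploid size `pop_size`, default 1,000) for
`drift_generations` (default 500).  Balanced sites are deterministically
pulled p ← p + s(p_eq − p) each generation before sampling (p_eq = 0.5 on
the minor-allele side, s = `balancing_strength`, default 0.05) — a
one-parameter scheme monotone in s.  After drift, a small fraction
(`allele_mismatch_rate` = 0.02) of neutral polymorphic sites gets a
non-matching alternate allele, exercising the allele-identity rule
(those sites are assigned MAF = 0 downstream).  Panel haplotypes are
drawn independently per site at the final frequency, so comparison panels
carry *no* within-panel LD; LD-based analyses are therefore tested on
haplotype panels built by the genotype generator instead.

**Annotations.** Functional categories are i.i.d. draws from a
configurable mix (defaults loosely Drosophila-like, ~5% missense); genes
tile arms in 5-kb slots; sex bias is a two-component mixture (30% biased,
SD 2 on log2 scale; else SD 0.2); tissue expression is Gamma(1.5, 10)
over 8 tissues; PPI counts are negative binomial; the linked-selection
track is an AR(1) (ρ = 0.9) over 1-kb windows mapped to a positive scale.
The generator does not model the correlation between annotation classes
and recombination/diversity present in real genomes; enrichment tests on
synthetic data validate machinery, not biology.

## Quantitative genetics (`quantgen`)

Bivariate Gibbs sampler for Y_ijk = X_ij + ε_ijk, X_j ~ N(0, G),
ε ~ N(0, σ²_{R,i}), residuals uncorrelated across sexes.  Priors:
inverse-Wishart(ν = 3, V = 0.1·I) on G and inverse-gamma(0.001, 0.001)
per residual variance — weakly informative; estimates at n = 200 lines
are insensitive to them but would be prior-dominated below ~30 lines.
Defaults 13,000 iterations / 3,000 burn-in / thin 10 (all configurable);
the test-suite and pipeline use shorter chains (2,500–4,000 iterations),
which at these data sizes give effective sizes of hundreds and stable
posterior means.  Point estimates are posterior means; intervals are 95%
highest-posterior-density (shortest-interval estimator).  h² uses the
hemiclone factor 2 (assayed individuals share the hemiclonal half of
their genome); values above 1 are possible by construction and flagged.
r_mf is Cov/√(σ²_m σ²_f) per draw, flagged undefined when either genetic
variance collapses below 1e-8.

## Association (`assoc`)

* **LD weights**: w_j = 1/(1 + Σ_k r²_jk) over neighbours within 100 kb —
  a transparent stand-in for LDAK's solver; duplicated SNPs share weight
  exactly (1/k each).
* **Kinship**: column j of Z is √w_j (x_j − p_j)[p_j(1−p_j)]^{α/2},
  α = −0.25 by default; K = ZZᵀ normalised to mean diagonal 1.  Missing
  genotypes are mean-imputed per site before kinship/association (they are
  <5% after QC).
* **REML**: single-component fits profile the likelihood over the variance
  ratio on the eigenbasis of K (the model has no fixed effects beyond
  centring, so ML on centred data is the restricted likelihood);
  convergence tolerance 1e-10 on the ratio, with an explicit boundary
  check at h² = 0.
* **GWAS**: EMMAX approximation — variance components fixed at the null
  fit, each SNP tested by GLS with V = σ²_g K + σ²_e I, Wald χ²₁ =
  (β̂/SE)².  With K = I this reduces exactly to per-SNP OLS effect
  estimates (dual-checked against `lstsq` oracles).  A floor of
  1e-8·max(σ²_g, 1) keeps the whitener nonsingular when REML hits the
  h² = 1 boundary.
* **Whitening permutations**: z = A⁻¹y with A = V^{1/2} (symmetric PSD
  square root) has identity covariance, so its entries are exchangeable;
  per-SNP statistics on permuted z give empirical p with the +1
  correction (minimum 1/(n_perm+1)).  Permutations are processed in
  blocks of 2,000 as one BLAS matmul each.
* **Window set-test**: the phenotype is whitened by the null background
  model, then each 1-kb window's standardised-genotype kinship is tested
  by one-component REML with a boundary LRT against the
  0.5χ²₀ + 0.5χ²₁ mixture.  Whether the original set-test kept window
  SNPs inside the background kinship is not documented anywhere we could
  follow; whitening by the genome-wide background (which includes them)
  is slightly conservative for large-effect windows, and the null
  simulations confirm the test is never anti-conservative.
* **Clumping** is the greedy textbook definition (best remaining p as
  index, claim neighbours within 10 kb with r² > 0.4); the positional
  clustering test permutes candidate labels within stratum (autosomes /
  X) and compares median adjacent distances.

## Partitioning (`partition`)

Multi-component REML optimises log-variances by L-BFGS on the explicit
n×n covariance (n ≤ a few hundred lines makes Cholesky per evaluation
cheap); standard errors come from the expected information
0.5·tr(V⁻¹K_i V⁻¹K_j), and share SEs by the delta method.  Expected class
shares are the class's fraction of LD-weight mass.  Circular permutations
rotate the annotation vector along genome order, preserving class counts
and LD exactly.  The sex-bias class test takes the background biased
fraction from nonantagonistic genes; the 2×2 overlap χ² uses no
continuity correction.  Quasi-Poisson PPI regression estimates dispersion
as Pearson χ²/df with a dispersion-adjusted F test.

## Balancing selection (`balsel`)

Analysis A stratifies control sites into 20 quantile bins of
linked-selection-residualised focal MAF and draws each null set without
replacement within a set, reproducing the candidates' bin histogram
exactly; the empirical p is one-sided (elevated MAF) by default, matching
the directional prediction, with a two-sided option.  Analysis B is a
logistic regression with an LRT (1 df) on |effect size|; complete
separation is detected and flagged rather than estimated.  Analysis C
draws one site per cell of a 20×100 (residual MAF × effect size) quantile
grid and reports Spearman's ρ.  Window diversity implements π, θ_W = S/a₁
and Tajima's D with the standard normalising constants; D is undefined at
S = 0 and such windows are excluded from regressions.  F_ST is Hudson's
estimator with sample-size correction, aggregated over windows as a ratio
of sums (ratio-of-averages), and compared between window classes by
Wilcoxon on linked-selection residuals (F_ST residuals are not confined
to [0, 1]).  The LD decay fit is a·exp(−d/b)+c by nonlinear least squares
seeded analytically (a = near-distance mean, c = far-distance mean,
b = half the distance range).  Trans-specific flags require shared
polymorphism *and* identical allele pairs.

## Problem sizes

Test and acceptance runs use the generator at 200 lines × 60–1,000
SNPs/arm, 25 observations per line and sex, 400–10,000 permutations and
25 pipeline replicates — sizes at which every statistical property under
test (calibration, recovery bands, power) is already stable.  The
end-to-end demo config runs the complete pipeline in well under a minute
and is bit-identical under reseeding.

## Known limitations

* The generator's comparison panels have no within-panel LD and no
  demographic structure; F_ST and LD-class analyses are validated on
  constructed haplotype panels.
* LD weights approximate, not replicate, LDAK's solver-based weights.
* The GWAS is single-trait on the antagonism index; bivariate
  (male, female) association and dominance components are out of scope.
* PCA outlier removal formalises a visual step as a 6-SD threshold on the
  leading PCs — a reproducible automation, not a reconstruction.
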