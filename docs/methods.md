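# Methods

`pairmeta` implements a pairwise cross-trait genetic analysis over GWAS
summary statistics: gene-based association under linkage disequilibrium
(LD), sample-size-weighted meta-analysis of gene statistics across two
traits, a filter for novel pleiotropic genes, LD score regression for
heritability and genetic correlation, a latent causal variable model for
causal direction, and competitive gene-set association. This note records
the models, the estimator choices, the defaults and their rationale, and
what the synthetic-data generator does and does not emulate.

## Gene-based association (Brown's method)

Per-SNP two-sided p-values inside a gene are converted to 1-df chi-square
quantiles, `q_i = [Φ⁻¹(1 − p_i/2)]²` (equal to `z_i²` when a signed Z is
available — the implementation prefers the signed route, which is exact),
and summed: `T = Σ q_i`. Under the null with SNP correlation matrix `R`,
`T ~ Σ λ_k χ²₁` with `λ_k` the eigenvalues of `R`. The tail is approximated
by a two-moment gamma (Brown's method): mean `Σλ = k`, variance `2Σλ²`.
Properties that matter:

- With identity LD the gamma *is* the exact chi-square_k law — no
  approximation error in the independence case (tested to 1e-10 relative
  for k ≤ 50).
- Under AR(1) LD the approximation is validated against a Monte-Carlo
  estimator (`monte_carlo_gene_pvalue`, add-one estimator over draws of
  `Z ~ N(0, R)`), holding `|log₁₀(p_brown/p_mc)| < 0.15` for p > 1e-4
  across random fixtures. The Monte-Carlo route is a validation oracle,
  not the inference path.
- Tail arithmetic is in natural-log space end to end (`gamma.logsf`,
  `ndtri_exp`), so the probit Z of a deeply significant gene never
  underflows; stored p-values are clamped into `(0, 1]` at the smallest
  positive float.

Genes overlapping the extended MHC (chr6:28,477,797–33,448,354, hg19,
1-based closed, any-overlap rule) are excluded before testing: its extreme
long-range LD is not representable by block nulls. The Bonferroni threshold
is `alpha / n_genes_tested` over the genes actually tested; both the count
and the threshold are reported. SNP-to-gene assignment uses 1-based closed
intervals with a symmetric flanking window, default 0 kb, recorded in the
annotation.

## Pairwise meta-analysis

Gene p-values are probit-transformed to one-sided Z-scores,
`z = Φ⁻¹(1 − p)`, and combined across the two traits by the
sample-size-weighted inverse-normal (Stouffer) rule

    z_meta = (√N₁ z₁ + √N₂ z₂) / √(N₁ + N₂),

with `N_i` the GWAS sample sizes (cases + controls for case-control
studies; effective-N weighting is available as an option but is not the
default). This is the weighting that reproduces the published worked
examples to ~1% and matches the convention of standard gene-based
meta-analysis software. Combination is one-sided throughout because gene
p-values are inherently one-sided.

The Cauchy combination (ACAT) is the companion method:
`T = Σ w_i tan((0.5 − p_i)π)` with `w_i = N_i/ΣN`, and
`p_meta = 0.5 − arctan(T)/π`. Numerical substitutions: `tan((0.5 − p)π) →
1/(pπ)` below p = 1e-15 (saturating at p ≈ 1e-300 so `T` stays finite even
for underflowed inputs) and the Cauchy upper tail `1/(Tπ)` for very large
`T`. Its value: the heavy Cauchy tail makes the combined p-value
insensitive to dependence between the inputs, so it stays calibrated under
sample overlap where the Stouffer rule is anti-conservative (measured in
the acceptance suite: at gene-score correlation ~0.3 the Stouffer level at
nominal 5% is ~7.4% while Cauchy is ~5.5%). Method agreement is summarised
by the Pearson correlation of −log₁₀ p with a Fisher-z 95% CI
(`SE = 1/√(n−3)`).

A gene is a **novel pleiotropic signal** for a pair iff

1. `p_meta < alpha_gene` (gene-level Bonferroni),
2. `p < 0.05` in *both* single-trait runs (nominal evidence in each), and
3. `p ≥ alpha_gene` in *both* single-trait runs (Bonferroni-significant in
   neither alone).

Condition 2 guards against genes carried entirely by the better-powered
trait; condition 3 restricts to associations that only emerge jointly.
Recurrence of retained genes across trait pairs is counted separately.

## LD score regression

Single trait: `E[χ²_j] = 1 + N h² ℓ_j / M`, with `ℓ_j = Σ_k r²_jk` the LD
score. A single weighted least-squares fit with a free intercept estimates
`h²` from the slope; heteroskedasticity weights `1/(1 + N h² ℓ/M)²` are
iterated twice from an unweighted start. The original LDSC software's
two-step estimator (intercept from χ² < 30 SNPs, then a constrained slope)
is deliberately **not** implemented — at desk scale the single free-intercept
regression is adequate and simpler, and the intercept remains available as
a confounding diagnostic. Cross-trait:
`E[z₁_j z₂_j] = √(N₁N₂) ρ_g ℓ_j / M + c`, where the intercept `c`
estimates `r_pheno · N_overlap/√(N₁N₂)` — the sample-overlap term — and
`r_g = ρ_g/√(h²₁h²₂)`. Cross-regression weights are the geometric mean of
the per-trait weights, which is symmetric in the traits and makes a trait
paired with itself return exactly `r_g = 1`. A cross-intercept with
two-sided p < 0.01 flags the pair as overlap-affected, which is the cue to
prefer the Cauchy meta-analysis.

Standard errors come from a delete-one block jackknife over contiguous SNP
blocks (default 200, minimum 20), with regression weights frozen at the
full-data fit; for `r_g` the jackknife re-estimates both heritabilities and
the genetic covariance per deleted block, so the SE propagates all three
regressions. Estimates of `|r_g|` up to 1.25 are tolerated numerically with
a warning above 1.

Pre-regression QC keeps SNPs with MAF strictly above 0.05, inside an
optional whitelist (HapMap3-style), and outside the MHC; fewer than 200
survivors is an error.

## Latent causal variable model

Two correlated traits share a latent component with loadings `q₁, q₂`
(`q₁q₂ = r_g`). The genetic causality proportion (GCP) `g ∈ [−1, 1]`
parameterises `q₁ = |r_g|^{(1−g)/2}`, `q₂ = |r_g|^{(1+g)/2}`: `g = 1` means
trait 1 fully causal for trait 2, `g = 0` symmetric pleiotropy. With a
kurtotic (sparse) effect distribution the mixed fourth *cumulants* of the
normalised effect pair are `K₁ = κ q₁³q₂`, `K₂ = κ q₁q₂³` (`κ` ≥ 0 the
latent excess kurtosis), so their asymmetry `K₁/K₂ = (q₁/q₂)²` identifies
the causal direction; Gaussian effects (`κ = 0`) make GCP unidentifiable,
as does `|r_g|` below 0.05 (an error).

Estimation: Z-scores are normalised to unit per-SNP genetic variance,
`a_ij = z_ij/√(N_i ĥ²_i ℓ_j/M)`; moment averages are LD-weighted (`1/ℓ_j`)
and the cumulants are formed as `K₁ = E[a₁³a₂] − 3·E[a₁²]·E[a₁a₂]` — exact
fourth-cumulant subtraction, so Gaussian sampling noise *and* Gaussian
sample-overlap noise cancel in expectation without any explicit
overlap correction. A delete-one block jackknife gives the 2×2 covariance
of `(K₁, K₂)`. The posterior over `g` is computed on a grid (step 0.01,
uniform prior): at each grid point the nuisance scale `κ` is profiled by
non-negative GLS and the likelihood is the bivariate normal density of the
observed cumulants under the jackknife covariance. Reported: posterior
mean GCP, posterior SD as its SE, and a two-sided normal test of GCP = 0.
The exact moment weighting of the original LCV software is not described
in the source material for this package; the grid-posterior construction
above is this package's own operational definition, and its validity rests
on simulation recovery (fully causal architectures are detected with
GCP > 0.6 in ≥80% of replicates; symmetric pleiotropy stays within
|GCP| ≤ 0.3), not on numeric identity with other implementations. Negative
`r_g` is handled by flipping trait 2's sign before fitting (the cumulants
flip with it), leaving the causal direction unchanged. Results carry a
caution flag when either trait's heritability Z-score (`h²/SE`) is below
7, the conventional reliability floor for this model; the flag for
"partial genetic causality" requires a significantly non-zero GCP *and*
`|GCP| > 0.6`.

## Competitive gene-set association

OLS of per-gene probit Z on `[intercept, membership, covariates]` with a
one-sided upper-tail t-test of the membership coefficient (enrichment
only). Default covariates: gene size (SNP count), its log, and — when
available — aggregate minor-allele count and its log; collinear covariate
columns are dropped with a warning (with uniform synthetic gene sizes the
size covariates collapse into the intercept, which is the expected
behaviour, not a defect). Benjamini–Hochberg FDR is applied within each
collection (significant-set counts are reported per collection); sets
smaller than 3 genes after intersection with the analysed universe are
skipped and reported. When a meta-analysis run is compared against a
single-trait run, sets significant in the former but not the latter are
flagged novel.

## Synthetic-data generator

LD is block-diagonal with AR(1) blocks, `r_jk = ρ^{|j−k|}`. ρ may be a
scalar or a `(lo, hi)` range drawn per block from the seed. The range
matters: with one global ρ the LD scores are nearly constant across SNPs
and the LD score *regression* loses its lever arm (slope and intercept are
confounded); heterogeneous blocks restore identification, as heterogeneous
regional LD does in real genomes. Recovery studies use `(0, 0.9)`.

True standardised effects are drawn per SNP with variance `h²_i/M`, either
bivariate normal with correlation `r_g`, or through the latent-causal
architecture `a_i = q_i π + γ_i` with `π` point-normal (causal fraction
default 0.1 in the library; excess kurtosis `3(1−p)/p`). Marginal Z-scores
follow `z = √N·R·β + ε`, `ε ~ N(0, R)`, with cross-trait noise correlation
`r_pheno·N_overlap/√(N₁N₂)` — overlap is modelled only in this noise term,
never by simulating individuals. Sampling uses the symmetric PSD square
root of each block (eigenvalue clipping at zero; clipping beyond 1e-8 is
an error). One master seed; per-block child streams are spawned
deterministically, so extending the panel never changes earlier blocks'
draws (the emitted Z-scores still rescale with total M because per-SNP
effect variance is `h²/M` at fixed total heritability).

What the generator does **not** emulate: realistic human LD maps and
long-range LD, allele-frequency-dependent architecture, ancestry mixture,
case-control ascertainment, and cross-block LD. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to every artefact of real consortium
GWAS.

## Problem sizes and defaults

Test and acceptance runs use panels of 10,000–20,000 SNPs in 250–2,000
blocks, 50 replicates for genetic-correlation recovery, 25 per scenario
for causality recovery, and 10⁶ draws for the Monte-Carlo gene-p oracle —
sizes chosen so each property is measured with Monte-Carlo error small
against its tolerance while the whole suite runs in minutes. The analysis
scripts scale published GWAS sample sizes by one tenth, keeping single-
trait gene tests underpowered relative to the pairwise meta-analysis —
the regime the method exists for. Jackknife blocks default to 200
(contiguous, a proxy for genomic independence); grid step 0.01 for the
GCP posterior; all thresholds (gene Bonferroni, nominal 0.05, FDR 0.05,
rg gating) are config values recorded in output metadata.

## Known limitations

- The Brown gamma approximation degrades in the far tail (p < 1e-4 is
  validated only indirectly) and for near-singular LD; the Monte-Carlo
  estimator exists for spot-checks.
- The single-regression LDSC variant can trade intercept against slope
  when LD scores vary little; it reports, but does not constrain, the
  intercept.
- The GCP posterior is a grid approximation with a profiled scale; it
  reports evidence for a causal *direction*, not a causal effect size, and
  is unreliable when heritability Z-scores are low (flagged) or the
  effect distribution is near-Gaussian.
- Allele harmonisation across traits is intentionally not performed:
  mismatched panels or orientations are hard errors, not repairs.
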