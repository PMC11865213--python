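# Methods

This note records the models implemented in `salmofat`, the defaults and why
they were chosen, what the synthetic cohort does and does not emulate, and
the numerical decisions a maintainer would want written down.

## The synthetic cohort

The generator produces the population structure the downstream analyses
assume: `n_individuals` = 634 offspring of 39 sires × 48 dams (each dam
mated to one sire, giving up to 48 full-sib families), 610 genotyped, 48 of
those selected for expression and fatty-acid profiling, 55 % male. A single
master seed drives deterministic per-stage generators, so each stage is
reproducible in isolation.

**Genotypes.** Founders are drawn in Hardy–Weinberg proportions at per-SNP
frequencies uniform on `maf_range` (default 0.05–0.5); offspring receive
one allele from each parent (gene dropping). The default panel of 5,000
SNPs on 29 chromosomes is a scaled stand-in for a ~53 k array — dense
enough that the realised GRM is accurate for a pedigree of this depth,
small enough that a full QC→GRM→REML replicate takes ~1 s. Three kinds of
QC-violating SNPs are injected and labelled (`qc_spike`, default 50 each):
12 % missing calls (call rate 0.88), ~1 % heterozygote carriers (MAF ≈
0.008), and common SNPs with no heterozygotes (HWE χ² ≈ n). The violations
are constructed, not sampled, so downstream filter tests have guaranteed
positives.

**Phenotypes.** Additive values use an infinitesimal architecture: every
clean polymorphic SNP is causal with i.i.d. normal effects on the centred
allele-count scale, scaled so Cov(u) = σ²_g·G_VanRaden — exactly the model
GREML fits, which is what makes parameter-recovery experiments a clean test
of the estimator rather than of an architecture mismatch. Cross-trait
effects share a genetic correlation matrix; the default is the one-factor
form R = vv′ + diag(1 − v²) built from each trait's correlation with liver
fat (0.37 muscle fat, 0.31 body weight, 0.70 liver score, 0.25 HSI, 0.28
viscera score), which is positive semidefinite by construction and
reproduces the liver-fat row exactly. Residual correlations reuse the same
structure damped by 0.3 — the data behind a full residual matrix do not
exist, and correlations of this size keep residuals plausible without
driving any fit.

Trait defaults: liver fat mean 7.6 %, σ²_g = 2.59, σ²_e = 4.19 (h² = 0.38);
muscle fat 19.2 ± 3.0 (h² 0.43); body weight 3.56 ± 0.83 kg (h² 0.58);
latent liver and viscera scores ~N(3, 1) discretised to 1–5 (h² 0.28); HSI
0.8 ± 0.1 (h² 0.19). Sex effects are small (e.g. 0.3 % fat) and centred so
the population mean is unchanged. Liver fat passes through a soft floor,
`floor + s·softplus((x − floor)/s)` with floor 4 % and softness 0.5,
reproducing the observed ~4 % physiological minimum and right skew; the
latent mean is solved by Gauss–Hermite quadrature so the *post*-transform
mean hits the configured 7.6 %. Because the rectification would bias
estimator-recovery experiments, `gaussian_traits=True` bypasses all
shaping; recovery tests and the acceptance script use that switch. The
stored liver score is oriented so higher = fattier; the raw 1–5 colour
scale is kept alongside (`liver_score_raw`, raw = 6 − stored), and
`reverse_liver_score` converts between them. HSI is re-derived from
simulated liver and body weights so the ratio arithmetic is exercised.

**Expression.** For the 48-fish subset, per-gene log2 abundance is normal
(mean ~N(4, 1.5²)); a configurable fraction of genes (default 10 %) is
linearly coupled to liver fat with coefficients ~N(0, 0.1) log2 units per
% fat; sex effects (~N(0, 0.1)) and full-sib family intercepts (variance
0.025, i.e. 10 % of the 0.25 residual log2 variance — the magnitude is not
identified by any published number) are added. Counts are Poisson at the
FPKM implied by gene length (0.4–8 kb) and library size (~2 M fragments),
so the normalisation stage can recompute FPKM from raw counts. Ten genes
are zeroed to exercise the degenerate-gene path. Truth labels (gene,
coupled?, coefficient) are returned for power/FDR checks.

**Fatty acids.** Nine named acids are drawn at the calibrated means/SDs
(e.g. 18:1n-9 at 22.4 ± 5.6 % of total fatty acids) with correlation to
liver fat of configurable sign — positive for 16:1n-7, 18:2n-6, 18:1n-9,
negative for 16:0, EPA, DHA, magnitude 0.6 — and each row is closed to
exactly 100 % through an "other" pool.

**What the generator does not emulate.** Linkage disequilibrium beyond
family co-segregation (founder haplotypes are exchangeable), selection,
epistasis, dominance, genotype–environment interaction, sequence-level
error, and RNA-seq artefacts (mapping bias, overdispersion beyond Poisson).
Passing tests therefore demonstrate correctness of the estimators under a
correctly specified polygenic model with realistic family structure — not
robustness to the full messiness of field data.

## Quality control

Call rate, MAF and HWE are computed per SNP over non-missing calls
(missing dosages are excluded from denominators, not imputed). Passing
requires call rate > 0.9, MAF > 0.02 and HWE p > 0.001, strict
inequalities. The HWE test is the 1-df Pearson χ² of observed vs expected
genotype counts (algebraically n·r² on the allelic correlation); an exact
test is available via `hwe_method="exact"` for small panels. In deep
full-sib designs the χ² rejects far more than its nominal rate — sibs are
correlated draws — so a family cohort loses noticeably more SNPs to the
HWE filter than an unrelated sample would; this mirrors what array QC does
on real sib material. SNPs with fewer than two calls get undefined metrics
and fail. A SNP failing several filters is counted once per filter and
once overall.

## GRM and principal components

G = ZZ′ / 2Σ pᵢ(1−pᵢ) with allele frequencies from the analysed sample
(no external reference panel exists for this design) and missing dosages
mean-imputed to 2p, which contributes zero to Z. Monomorphic SNPs raise an
error directing the caller to QC. Principal components are eigenvectors of
G scaled by √eigenvalue with a deterministic sign convention (largest
loading positive); the GWAS uses the top two as fixed covariates. Binary
I/O uses a row-major lower-triangle of little-endian float32 plus an id
sidecar; a square TSV dialect is also provided.

## REML

The univariate fit eigendecomposes G once and optimises (σ²_g, σ²_e) in the
rotated basis, where V is diagonal: one EM step as burn-in (slow but
globally stable), then average-information updates with step-halving so the
accepted restricted log-likelihood never decreases. Components are clamped
at 10⁻⁸ of the phenotypic variance and flagged when they sit on that
boundary (null simulations then run unattended instead of erroring).
Convergence is a relative log-likelihood change below 10⁻⁸, at most 100
iterations; non-convergence is flagged, not raised. Standard errors come
from the inverse AI matrix, SE(h²) by the delta method. `reml_loglik` is
exposed so grid searches can audit the optimiser. An optional log-transform
of the response supports the usual sensitivity check for skewed traits.

The bivariate fit exploits the same rotation: with both traits on the same
fish, V splits into n independent 2×2 blocks dᵢ·C_g + C_e, making each AI
iteration O(n). Records missing either trait are dropped (complete-case) —
that is what keeps the block structure exact, and every calibration target
involves complete records. Initial values come from the two univariate fits
with covariances at half the phenotypic correlation; C_g and C_e are kept
positive semidefinite by eigenvalue clipping (flagged when it bites), r_G
is clamped to [−1, 1] with a boundary flag, and SE(r_G) uses the delta
method on the genetic block. With freely estimated cross-covariances the
bivariate marginal of one trait is not *identical* to its univariate fit in
finite samples; they agree to ~10⁻² in h² at n = 300, which is the
tolerance the corresponding test uses.

## GWAS

Variance components are estimated once genome-wide and reused for every
leave-one-chromosome-out chromosome (re-estimation per chromosome is
available behind `per_chromosome_vc`). For chromosome c, G(−c) is built by
subtracting that chromosome's ZZ′ block and its share of the denominator;
each SNP on c is then tested by GLS under V(−c), with α̂ = s′Py / s′Ps and
Var(α̂) = 1/s′Ps — algebraically identical to fitting the SNP jointly with
the covariates, which the oracle tests verify to 10⁻⁸. SNPs without genome
placement are tested against the full-genome GRM and reported in an
`unmapped` stratum. λ = median(χ²)/0.455, using the conventional printed
constant. Bonferroni cutoffs are α/t_g and α/t_c with t_c the average SNP
count per chromosome. Candidate-gene scans rank SNPs by ascending p (ties:
chromosome, position, id) and intersect closed ±200 kb windows, clipped at
position 1, with closed gene intervals (1-based, inclusive — a gene ending
exactly at pos − 200,000 is reported). Manhattan/QQ exports use cumulative
positions with the unmapped stratum last and expected quantiles
−log10((i−0.5)/m).

Under permuted phenotypes the scan is calibrated (λ within 0.1 of 1, 5 %
type-I rate within binomial error). Two small, understood effects move λ
in opposite directions in other settings: the non-negativity clamp on
σ̂²_g deflates tests slightly when the true genetic variance is zero in an
unrelated sample, and genuine polygenic signal inflates the median χ² —
λ > 1 on the simulated cohort is expected, not evidence of
stratification.

## Expression association

Size factors are median-of-geometric-means over reference genes (genes
with positive counts in every sample); they are defined up to a common
scale, so only ratios are meaningful. FPKM uses the normalised library
size sf_j · median_k(lib_k/sf_k), making expression invariant to
depth-only differences, and log2(FPKM + 1) is the analysis scale (the
pseudocount handles zeros; no published choice exists). Genes expressed in
under half the samples are dropped by default; the filter is configurable
because the corresponding QC step in real pipelines is rarely specified
exactly.

The per-gene model profiles the family-to-residual variance ratio γ by
restricted likelihood (coarse log-grid, then bounded refinement), using one
eigendecomposition of the family incidence shared across genes. When the
optimum is at γ = 0 the fit *is* OLS, bit for bit — with ~48 fish spread
over almost as many families this is the common case and is tested as a
first-class path. Wald p-values use a normal reference by default with a
t(n−p) option; at n = 48 the normal is mildly anticonservative (~5.9 % at
the 5 % level on i.i.d. nulls) and the t reference is calibrated.
Significance is raw p < 0.05 with no multiple-testing correction, matching
how trait-associated gene lists of this kind are defined. One caveat
surfaced by the null simulations: relatedness beyond full sibs (half-sib
ties through shared sires, founder kinship) is not absorbed by the family
intercept, leaving a little extra dispersion on pedigreed cohorts (~6–7 %
rejections at nominal 5 %). That is a property of the published model
itself; users who need exact calibration on deep pedigrees should prefer
the GREML machinery, which models the full GRM.

## Enrichment and descriptives

Each term is a 2×2 table (in-term vs out-of-term × significant vs not)
over the background of retained genes — the conventional reading; the
background is configurable. Terms with fewer than five background genes
are skipped without a p-value. Yates' correction subtracts N/2 from
|ad − bc| and clamps at zero; a degenerate margin (e.g. significant set =
background) skips the term with a warning. The `enriched` flag is p < 0.05
as defined for this analysis; a `direction` column distinguishes over-
from under-representation. Spearman correlations use midranks with the
t-approximation p; HSI = liver weight / body weight × 100.

## Problem sizes

Defaults were chosen so a complete QC → GRM → REML replicate at 600 fish ×
5,000 SNPs runs in about a second and the 20-replicate recovery studies in
under a minute: with ~87 founders the realised relationship matrix is
already well estimated at a few thousand markers, so larger panels add
runtime, not information. The acceptance script uses exactly these sizes.

## Known limitations

- Bivariate REML is complete-case; records with one missing trait are
  dropped rather than modelled.
- No dominance or epistatic components; no more-than-two-trait REML.
- The GWAS offers Wald tests only (no score test), and PCs always derive
  from the GRM rather than LD-pruned genotypes — with a family design and
  no external panel there is nothing else to derive them from.
- The HWE "correlation p-value" of array-vendor QC is interpreted as the
  standard 1-df Pearson χ² (with an exact-test switch); vendor-specific
  variants are not reproduced.
- The per-gene family intercept under-corrects deep-pedigree relatedness
  (see above).
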