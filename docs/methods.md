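# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical and design choices behind `csf_scqtl`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Genotype QC and kinship

Genotypes are expected as imputed dosages (expected alt-allele count in
[0, 2]) with a per-call posterior probability and a per-SNP imputation info
score. QC masks calls with posterior < 0.4, removes SNPs with info score
R² < 0.6, and removes SNPs whose hard-called genotype counts fail a
1-df chi-square Hardy–Weinberg test at p < 1e-4. These are conventional
post-imputation array-QC thresholds; a chi-square (rather than exact) HWE
test is adequate at cohort sizes of ~80 donors. Monomorphic sites are kept
(expected heterozygote count 0, observed 0 — consistent). QC is idempotent.

The kinship matrix is the standardized genetic relationship matrix
`K = ZZᵀ/m` with columns standardized using the population (ddof 0)
standard deviation, so the diagonal mean is exactly 1. Missing dosages are
mean-imputed for kinship only; per-SNP association drops those donors
instead (no imputation bias in the test itself). Zero-variance SNPs are
skipped.

## Normalization and pseudobulk

Two normalizations are provided. The default, `pearson_nb`, computes
per-gene negative-binomial Pearson residuals with expected counts from a
log-depth offset model (`μ_ig = depth_i · p_g`), a per-gene moment estimate
of the dispersion `α` in `var = μ + αμ²`, regularized by a running median
over genes ordered by log mean expression, and residuals clipped at
±√(#cells). This is a deliberate simplification of regularized-NB
normalization: the downstream mixed model needs approximately
variance-stabilized donor means, not any particular tool's exact output.
`log_cp10k` (log1p of depth-normalized counts × 10⁴) is the alternative;
it is the right scale when the quantity of interest is a log fold change
(see the eQTL recovery benchmark below). All-zero genes get residual 0.

Aggregation takes the mean of normalized values over a donor's cells of
one cell type. Donors with fewer than 2 cells of the type are dropped;
genes with non-zero raw expression in fewer than 10% of the *retained*
donors are dropped (the gene filter runs after the donor filter, per cell
type, so power differs between cell types). The per-donor summed raw UMIs
are kept as the `n_i` entering the read-depth random effect.

## The cis-eQTL mixed model

Per gene and cell type, donor-level expression is modelled as

    y = Xb + g_kin + g_depth + e,   cov(y) = σ²_g K + σ²_d D + σ²_e I,

with `D = diag(1/n_i)`. The null model (no genotype) is fit by REML,
parameterized as `σ²_e (I + γ_g K + γ_d D)` with the ratios optimized on
the log scale: a 5×5 coarse grid over log γ ∈ [−8, 3] followed by
Nelder-Mead polish, profiling out σ²_e analytically. Ratios below 1e-6 are
truncated to exact zeros. When read depths are similar across donors, D is
nearly proportional to I and σ²_d/σ²_e are only weakly separately
identified; their combined contribution is what the downstream test uses,
so this is harmless (and asserted as such in the tests).

Each cis SNP (gene body ± 100 kb, boundary-inclusive, MAF ≥ 10%) is tested
by GLS with the null covariance held fixed: the model is whitened by the
Cholesky factor of Σ̂, refit by least squares with the residual scale
re-estimated (so the test reduces *exactly* to OLS when both variance
components are zero), and the Wald p uses the standard normal reference —
any residual miscalibration is absorbed by the permutation layer.

**Gene-level permutation.** The observed statistic is the minimum nominal
p over cis SNPs (equivalently the maximum |partial correlation| in the
whitened space, since all SNPs share the residual df). The null replays
the same minimum under donor-label permutations shared across SNPs,
preserving LD. Permutation happens *after* whitening: the decorrelated
donor residuals are exchangeable under the fitted null, whereas raw
expression is not when kinship or depth variance is present — permuting
raw y produced measurably non-uniform null p-values in development, and
permuting whitened residuals (re-projected onto the orthocomplement of the
fixed effects after shuffling) restored KS uniformity across seeds.
`p_perm = (1 + #{null_min ≤ obs_min}) / (n_perm + 1)` with 1000
permutations by default. Missing dosages are mean-imputed within SNP for
this vectorized scan only.

**Across genes.** Storey q-values with π₀ estimated at a single fixed
λ = 0.5 (robust at small gene counts), capped at 1. The conditional-FDR
variant stratifies genes by external reference evidence (reference p below
a Bonferroni threshold 0.05/#reference genes by default), applies Storey
within the conditioned stratum, and routes all remaining genes — including
those absent from the reference — through the plain Storey branch. Both
are controlled at 10%. This stratified construction is a declared
approximation: conditional FDR is named but not algorithmically pinned
down in the literature this pipeline follows. Replication against an
external study requires a concordant effect direction and nominal p < 0.05
after allele harmonization (the external β flips sign when ref/alt are
swapped).

## Fine-mapping

The sum-of-single-effects model: the effect vector is `Σ_l b_l` where each
`b_l` is nonzero at a single SNP with a `N(0, σ²_0l)` prior and a uniform
prior over which SNP. The iterative Bayesian stepwise fit updates each
effect on residuals via Bayes-factor-weighted single-effect regression;
the prior variance per effect is optimized by a bounded 1-d search on the
log scale and set to zero when it does not improve on the null
single-effect likelihood (so null data yields no active effects). The
residual variance is updated each outer iteration from the expected
residual sum of squares, and the loop stops when the evidence lower bound
changes by less than 1e-3 (default; max 100 iterations, flagged if hit).
Defaults L = 10, 95% coverage, purity ≥ 0.5 mirror the published defaults
of credible-set fine-mapping software. Credible sets are the smallest
posterior-ordered SNP sets reaching coverage per active effect,
de-duplicated, with purity the minimum absolute pairwise dosage
correlation (clipped to [0, 1]; singleton sets have purity 1). PIPs
combine effects as `1 − Π_l (1 − α_lj)` over active effects. Zero-variance
dosage columns are dropped (PIP 0). Duplicate SNPs with one causal signal
force the α = (½, ½) split by symmetry — checked against an explicit
Bayes-factor oracle in the tests.

GWAS overlap annotation flags, per fine-mapped gene, whether any GWAS
variant lies within 100 kb of the gene's cis region and whether one is a
member of a credible set.

## Beta-binomial tests (ASE and transcript usage)

One parameterization is shared repo-wide: mean μ, overdispersion
φ ∈ [0, 1), `α = μ(1−φ)/φ`, `β = (1−μ)(1−φ)/φ`. For φ < 1e-6 the
distribution is treated as an exact binomial: beyond that point the beta
shape parameters exceed ~10⁶, where the beta-binomial pmf evaluation loses
precision while its true difference from the binomial is O(n²φ). (This
threshold matters: with the boundary handled naively, the numeric Hessian
at φ̂ ≈ 0 was corrupted by pmf round-off and standard errors could come out
several-fold too small.)

ASE fits `logit(μ) = b0` with a φ shared across donors (donors are
replicates of one SNP's imbalance), on donor-pseudobulk (alt, total) UMI
counts from heterozygous donors; testing "mean allele fraction = 0.5" is
testing b0 = 0. The usage test fits `logit(ψ) = b0 + b1·dosage` on
donor-level two-isoform counts and tests b1 = 0. Optimization is
Nelder-Mead on the unconstrained `(b, logit φ)` scale from two starts (the
pooled binomial estimate with φ = 0.02 and with φ = 0.1); standard errors
come from the observed information (numeric Hessian), falling back to the
coefficient-block information at fixed φ when the joint information is
singular at the φ boundary, and to a binomial GLM (flagged) if that also
fails. Wald p-values use a t reference with df = donors − coefficients:
at the 10–40 heterozygous donors typical of pseudobulk ASE, the normal
reference is measurably anti-conservative (~0.065 at nominal 0.05 in the
calibration battery) and the t reference restores nominal level. Tests
below 2 informative donors or 5 pooled UMIs are skipped.

When several candidate SNPs tag one gene, the one maximizing the number of
donors that are heterozygous *and* covered by at least one UMI is chosen;
ties break to the smallest genomic position. ASE significance flags are
BH-FDR per cell type at 0.01 and 0.0001.

## Factor-model statistics

The factorization (cell × factor values Z, gene × factor weights W) is an
input. Variance explained per factor and cell type is
`R²_f = 1 − ‖Y − z_f w_fᵀ‖²/‖Y‖²` on the column-centered expression the
model was fit to, with factor values centered within the cell-type subset;
unrelated factors score ≤ 0 and the retention threshold is 1%. Disease
association averages a factor per donor over that donor's cells of the
tested cell type, takes the regression coefficient on the case indicator,
and permutes donor group labels (10 000 by default; empirical p with the
(1+x)/(1+N) floor; ≥ 3 donors per group required; BH FDR at 10% across
tested pairs). Regulon enrichment scores `S = WᵀT` (the plain sum of
weights over targets — a mean-aggregation option exists for TF-size
comparability) against 10 000 random same-size gene draws from the shared
universe; the two-sided empirical p uses a small tolerance in the
exceedance comparison so a null draw that recomposes the observed target
set counts as an exceedance despite summation-order rounding (the
TF-whose-targets-are-the-universe case must give p = 1 exactly). TFs with
fewer than 3 targets in the universe are dropped. The |weight| gene-set
test is a competitive Mann-Whitney of member vs non-member |w|, BH
corrected, skipping sets that overlap the universe in < 3 genes or cover
it entirely.

## Viral models

Donor presence is ≥ 1 summed UMI for the virus across the donor's cells;
viruses prevalent in strictly more than 5% of either the MS or the non-MS
cohort are tested. The donor-level logistic model is
`Virus_present ~ is_MS + total_UMIs + intercept` with `total_UMIs` the
donor's total transcriptome UMIs (depth confounder; configurable), Wald p
on `is_MS`, BH FDR at 10%. Under (quasi-)separation a Firth-penalized fit
(Jeffreys-prior score adjustment via the hat-diagonal half-weight
correction) is reported with a flag. The cell-level model regresses the
per-donor fraction of virus-positive cells (any virus) on `is_MS` with log
total UMIs and log cell count as covariates (OLS; residual df =
donors − 4); all-zero proportions return coefficient 0, p = 1, flagged
degenerate. The raw-vs-log ambiguity in the donor-level model's depth
covariate is resolved by following the two model formulas as printed: raw
totals in the logistic model, logs in the linear one.

## The synthetic-data generator

The generator is the package's test bed and defines the conditions under
which the recovery claims hold.

*Genotypes.* Haplotype alleles within an LD block share a latent Gaussian
factor with loading √ld_rho; an allele is the indicator that the latent
value falls below the allele-frequency quantile and dosage is the sum of
two independent haplotypes — Hardy-Weinberg by construction within a
population, with pairwise dosage correlation controlled by ld_rho. Two
ancestral populations with Balding-Nichols divergence F = 0.05 (optional,
a free parameter not calibrated to any cohort) make the kinship random
effect non-trivial. Defaults: 81 donors in groups (33, 16, 16, 16) for
(MS, OIND, NIND, IIH), 2000 SNPs in 100 blocks at 5 kb spacing, MAF drawn
from (0.1, 0.5), imputation R² from U(0.5, 1) (planted SNPs forced ≥
0.95), 2% of calls given low posteriors to exercise QC.

*Expression.* Cell counts are negative-binomial with
`mean = depth_i · exp(a_g + b_dg + β·dosage)` — gene baseline a_g ~
N(−1.2, 1), donor-gene random effect b_dg ~ N(0, 0.3), lognormal cell
depth factor (sd 0.3), dispersion 0.5 (var = μ + 0.5μ²) — with planted
eQTL terms applied only in their designated cell type. 3 cell types,
50–200 cells per donor.

*Allelic, isoform, factor and viral layers.* Heterozygous donors (hard
call 1) get NB totals (mean 30) and beta-binomial alt counts at the
planted (mean_AF, φ), null SNPs at 0.5; isoform counts put a
dosage-indexed long-isoform share (default the 0.913/0.83/0.738 triple)
on Poisson per-cell totals with φ = 0.02; the factor model has N(0, 1)
weights with planted regulon targets shifted by +2, a planted
disease-associated factor (donor-level +1 shift for MS in one cell type),
and the "matrix the model was fit to" is its own reconstruction ZWᵀ plus
unit noise so each of the 30 factors explains a meaningful variance share;
the viral matrix is sparse (per-cell presence logit ~ N(−6, 0.7)) with a
+1.5 log-odds shift for MS cells.

What the generator does **not** emulate: read-level data (FASTQ/BAM),
doublets, ambient RNA, cell-type-specific abundance imbalance, realistic
library-size heterogeneity beyond the lognormal factor, multi-allelic
sites, or LD patterns from a real reference panel. Passing recovery tests
therefore demonstrates the correctness and calibration of the statistical
machinery under its stated model, not robustness to the full messiness of
real droplet data.

Determinism: every generator stage derives its RNG from (seed, stage
offset), so identical configurations reproduce bit-identical outputs and
each stage is independently reproducible. Ground truth (planted lists,
realized planted-SNP dosages, donor-level true log means) is serialized to
YAML alongside the dataset.

## Calibration battery and problem sizes

`csf_scqtl.validation` holds the simulation benchmarks run by both the
acceptance tests and `scripts/acceptance.py`: 1000 null genes (80 donors,
two-population kinship, lognormal read depths) for mixed-model type-I
error and 500 genes × 1000 permutations for KS uniformity; 50 replicates
of a planted β = 0.8 eQTL at MAF 0.3, 80 donors × 50 cells for recovery
and effect-size bias — this benchmark uses log-CP10K normalization and a
high-expression planted gene (per-cell mean ~12 counts), because the
planted effect is a log-scale fold change and the log-scale estimator is
consistent there, while Pearson residuals estimate on a standardized scale
not comparable to the planted value; 1000 balanced ASE tests at 30 donors,
φ = 0.1 for null calibration plus a dense (b0, φ) likelihood-grid oracle;
200 single-causal fine-mapping replicates (n = 150, β = 0.6, 50 SNPs) for
credible-set coverage; a 2000-gene universe with a planted 50-gene regulon
at +2 for enrichment; and 400 donors with a planted 1.5 log-odds shift for
the viral logistic model. These sizes keep the full battery at a few
minutes on one CPU while leaving the Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

- The permutation layer holds kinship with the genotypes, so it tests the
  no-association null including relatedness; exchangeability is exact only
  under the *fitted* covariance.
- cFDR is a stratified approximation (see above), not a likelihood-based
  conditional FDR.
- The usage model supports exactly two transcript groups.
- Donor-specific overdispersion in the beta-binomial tests is out of
  scope (φ is shared within a test).
- The Wald t reference is a pragmatic small-sample calibration; a
  likelihood-ratio test would be the next refinement.
- X-chromosome handling, multi-allelic sites and trans-eQTLs are out of
  scope.
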