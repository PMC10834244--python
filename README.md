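# csf-scqtl

Downstream statistical genetics for cerebrospinal-fluid (CSF) single-cell
RNA-seq cohorts — the analyses that sit between a processed cell-by-gene
count matrix plus imputed donor genotypes and the biological conclusions:

- **Pseudobulk cis-eQTL mapping** per cell type with a linear mixed model
  carrying two random effects: donor relatedness (kinship `K`) and per-donor
  read depth (`D = diag(1/n_i)`), i.e. `cov(y) = σ²_g K + σ²_d D + σ²_e I`.
  Variance components are estimated once per gene by REML; each SNP in the
  ±100 kb cis window (MAF ≥ 10%) is tested by generalized least squares;
  gene-level multiplicity is handled by a 1000-permutation min-p scheme and
  study-wide multiplicity by Storey q-values or a conditional-FDR variant
  stratifying on an external reference study (both at 10%).
- **Fine-mapping** of cis signals by a sum-of-single-effects Bayesian
  regression (L = 10 effects, 95% credible sets, purity ≥ 0.5) with
  annotation of overlap with GWAS susceptibility variants.
- **Allele-specific expression (ASE)**: beta-binomial regression of donor
  pseudobulk (alt, total) UMI counts at heterozygous SNPs, testing whether
  the mean allele fraction departs from 0.5 (Wald test on the logit-scale
  intercept; BH FDR flags at 0.01 and 0.0001).
- **Transcript-usage QTLs**: beta-binomial regression
  `logit(ψ) = b0 + b1·dosage` on two-isoform transcript-compatible counts.
- **Factor-model statistics** (the factorization itself, e.g. MOFA+, is
  consumed, not fit): per-cell-type variance-explained filtering (≥ 1%),
  donor-level permutation tests of disease association, transcription-factor
  regulon enrichment via the matrix product `S = WᵀT` against 10 000 random
  gene sets of matched size, and a competitive |weight| gene-set test.
- **Viral prevalence models** on a cell-by-virus UMI matrix: the donor-level
  logistic model `Virus_present ~ is_MS + total_UMIs + intercept` (with a
  Firth-penalized fallback under separation) and the donor-level linear model
  `viral_proportion ~ is_MS + log total UMIs + log cell count`.
- A **synthetic-data generator** that emulates every input with planted,
  recorded ground-truth effects — LD-structured dosages from a Gaussian
  copula, negative-binomial counts with donor random effects, beta-binomial
  allelic imbalance, genotype-dependent isoform usage, planted regulon
  loadings and group-shifted viral UMIs — so every analysis is testable for
  recovery without access to any controlled human data.

The beta-binomial is parameterized repo-wide by mean μ and overdispersion
φ ∈ [0, 1) with `α = μ(1−φ)/φ`, `β = (1−μ)(1−φ)/φ`; φ → 0 recovers the
binomial.

## Worked example

The `demo` subcommand simulates a compact cohort (60 donors in four disease
groups, 3 cell types, 400 SNPs, 60 genes), runs every stage and prints a
recovery report:

```sh
csf-scqtl demo --out demo_run --seed 1
```

```
analysis          target                  planted                           detected  significant
    eqtl  gene0010@T_CD4                 beta=0.8                beta=0.671 q=0.0579         True
     ase        snp00399                   AF=0.7              AF=0.718 fdr=8.72e-09         True
   usage        gene0020 psi=(0.913, 0.83, 0.738) psi=(0.906,0.831,0.716) p=3.65e-09         True
 regulon    factor0/TF00                shift=2.0                           p=0.0005         True
   viral cell_proportion       log-odds shift=1.5             coef=0.2377 p=6.29e-19         True
```

Reading the rows: the planted cis-eQTL (log fold change 0.8 per alt allele
in CD4 T cells) is recovered at 0.671 with gene-level Storey q = 0.058,
below the 10% FDR rule; the allelic-imbalance SNP planted at allele
fraction 0.7 is estimated at 0.718 and flagged far below FDR 0.01; the
usage QTL's per-genotype long-isoform shares come back within 0.022 of the
planted 0.913/0.83/0.738 with a strongly negative dosage slope; the planted
regulon sits at the empirical floor of 2000 draws; and the MS shift in the
proportion of virus-positive cells is detected by the cell-level model.

Each capability also has a narrative script under `examples/` (simulation,
eQTL scan, fine-mapping, ASE, transcript usage, factor enrichment, viral
models) that builds a small input, runs the method from Python and prints
what the numbers mean. Stage-level subcommands (`simulate`, `qc`,
`pseudobulk`, `eqtl`, `finemap`, `ase`, `usage`, `factors`, `viral`) expose
the same pipeline on files, and every output TSV carries a provenance
header with the package version, seed and parameters.

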