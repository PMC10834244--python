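"""Donor genotype I/O, QC filtering and kinship.

Genotypes are held as a dense donor x SNP dosage matrix (expected
alt-allele count in [0, 2], NaN for missing calls) alongside per-SNP
metadata and per-call posterior probabilities.  QC mirrors standard
post-imputation practice: drop low-confidence calls, poorly imputed
SNPs and SNPs out of Hardy-Weinberg equilibrium.  The kinship matrix is
the standardized genetic relationship matrix used as a random-effect
covariance in the eQTL mixed model.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

SNP_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "r2"]


@dataclass
class GenotypeTable:
    """Donor x SNP dosage matrix with SNP metadata.

    Parameters
    ----------
    donors : list of str
        Ordered donor identifiers (rows of ``dosage``).
    snps : pandas.DataFrame
        One row per SNP with columns ``id, chrom, pos, ref, alt, r2``
        (``pos`` 1-based, ``r2`` the imputation info score).
    dosage : ndarray of shape (n_donors, n_snps)
        Expected alt-allele counts in [0, 2]; NaN marks missing calls.
    call_posterior : ndarray, optional
        Per-call posterior probability of the hard call, in [0, 1].
    """

    donors: list
    snps: pd.DataFrame
    dosage: np.ndarray
    call_posterior: np.ndarray | None = None

    def __post_init__(self):
        self.snps = self.snps.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.donors), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.donors)} donors x {len(self.snps)} SNPs"
            )
        if self.snps["id"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        if (self.snps["pos"] <= 0).any():
            raise ValueError("SNP positions must be strictly positive (1-based)")

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        return replace(
            self,
            snps=self.snps.loc[mask].reset_index(drop=True),
            dosage=self.dosage[:, mask],
            call_posterior=None if self.call_posterior is None else self.call_posterior[:, mask],
        )

    def subset_donors(self, donors) -> "GenotypeTable":
        idx = [self.donors.index(d) for d in donors]
        return replace(
            self,
            donors=list(donors),
            dosage=self.dosage[idx],
            call_posterior=None if self.call_posterior is None else self.call_posterior[idx],
        )


@dataclass
class KinshipMatrix:
    """Symmetric PSD donor x donor genetic relatedness matrix."""

    donors: list
    K: np.ndarray

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.donors)
        if self.K.shape != (n, n):
            raise ValueError("K shape does not match donor count")

    def align(self, donors) -> np.ndarray:
        """Return K restricted/reordered to the given donor list."""
        idx = np.array([self.donors.index(d) for d in donors])
        return self.K[np.ix_(idx, idx)]


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value for Hardy-Weinberg equilibrium.

    Expected genotype counts come from the sample allele frequencies.
    Returns NaN when no genotypes are observed.
    """
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return np.nan
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    # monomorphic site: expected het count 0, observed 0 -> perfectly consistent
    nz = expected > 0
    chi2 = np.sum((observed[nz] - expected[nz]) ** 2 / expected[nz])
    return float(stats.chi2.sf(chi2, df=1))


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """MAF from dosages: min(f, 1-f) with f = mean(dosage)/2 over non-missing calls."""
    dosages = np.asarray(dosages, dtype=float)
    valid = dosages[~np.isnan(dosages)]
    if valid.size == 0:
        return np.nan
    f = valid.mean() / 2.0
    return float(min(f, 1.0 - f))


def hard_calls(dosages: np.ndarray) -> np.ndarray:
    """Round dosages to the nearest genotype in {0, 1, 2}; NaN propagates."""
    return np.clip(np.rint(np.asarray(dosages, dtype=float)), 0, 2)


def apply_genotype_qc(
    g: GenotypeTable,
    posterior_min: float = 0.4,
    r2_min: float = 0.6,
    hwe_alpha: float = 1e-4,
) -> GenotypeTable:
    """QC-filter genotypes: mask low-posterior calls, drop low-info and HWE-failing SNPs.

    Calls with posterior probability < ``posterior_min`` are set missing;
    SNPs with imputation R^2 < ``r2_min`` or with a Hardy-Weinberg
    chi-square p-value < ``hwe_alpha`` are removed.  Idempotent.
    """
    for name, thr in [("posterior_min", posterior_min), ("r2_min", r2_min), ("hwe_alpha", hwe_alpha)]:
        if not 0 < thr < 1:
            raise ValueError(f"{name} must be in (0, 1), got {thr}")
    dosage = g.dosage.copy()
    if g.call_posterior is not None:
        dosage[g.call_posterior < posterior_min] = np.nan
    keep = g.snps["r2"].to_numpy() >= r2_min
    calls = hard_calls(dosage)
    for j in np.flatnonzero(keep):
        col = calls[:, j]
        col = col[~np.isnan(col)]
        p = hwe_test(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        if np.isfinite(p) and p < hwe_alpha:
            keep[j] = False
    out = replace(g, dosage=dosage, call_posterior=g.call_posterior)
    out = out.subset_snps(keep)
    if out.n_snps == 0:
        warnings.warn("all SNPs removed by genotype QC", stacklevel=2)
    return out


def compute_kinship(g: GenotypeTable) -> KinshipMatrix:
    """Standardized genetic relationship matrix K = Z Z^T / m.

    Missing dosages are mean-imputed, each SNP column is standardized
    (population sd), zero-variance SNPs are skipped.  The diagonal mean
    is 1 by construction.
    """
    if g.n_donors < 2 or g.n_snps < 2:
        raise ValueError("kinship needs >=2 donors and >=2 SNPs")
    X = g.dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - col_mean[keep]) / sd[keep]
    m = Z.shape[1]
    if m == 0:
        raise ValueError("no polymorphic SNPs for kinship")
    K = Z @ Z.T / m
    return KinshipMatrix(donors=list(g.donors), K=K)


def snp_summary(g: GenotypeTable) -> pd.DataFrame:
    """Per-SNP summary: id, chrom, pos, maf, hwe_p, r2."""
    calls = hard_calls(g.dosage)
    rows = []
    for j, rec in g.snps.iterrows():
        col = calls[:, j]
        col = col[~np.isnan(col)]
        rows.append(
            dict(
                id=rec["id"],
                chrom=rec["chrom"],
                pos=int(rec["pos"]),
                maf=minor_allele_frequency(g.dosage[:, j]),
                hwe_p=hwe_test(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())),
                r2=rec["r2"],
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF I/O (simplified v4.2 with GT:DS:GP; DS preferred, GT fallback)
# ---------------------------------------------------------------------------

def write_vcf(g: GenotypeTable, path, r2_field: str = "R2") -> None:
    """Write a simplified VCF v4.2 with GT:DS:GP sample fields."""
    post = g.call_posterior
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f'##INFO=<ID={r2_field},Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        fh.write('##FORMAT=<ID=GP,Number=1,Type=Float,Description="Posterior of the hard call">\n')
        for chrom in pd.unique(g.snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.donors)) + "\n"
        )
        gts = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, rec in g.snps.iterrows():
            fields = []
            for i in range(g.n_donors):
                ds = g.dosage[i, j]
                gp = 1.0 if post is None else post[i, j]
                if np.isnan(ds):
                    fields.append("./.:.:.")
                else:
                    gt = gts[int(np.clip(np.rint(ds), 0, 2))]
                    fields.append(f"{gt}:{ds:.3f}:{gp:.3f}")
            fh.write(
                f"{rec['chrom']}\t{int(rec['pos'])}\t{rec['id']}\t{rec['ref']}\t{rec['alt']}\t.\t.\t"
                f"{r2_field}={rec['r2']:.4f}\tGT:DS:GP\t" + "\t".join(fields) + "\n"
            )


def read_vcf(path, r2_field: str = "R2") -> GenotypeTable:
    """Read a VCF into a GenotypeTable (DS preferred, GT fallback).

    Multi-allelic records are skipped with a warning.  The imputation
    info score is taken from the INFO field named ``r2_field``
    (configurable because real-data dialects vary: R2, INFO, DR2, ...).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    donors = list(vcf.samples)
    rows, dosages, posts = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multi-allelic site {var.ID or var.POS}", stacklevel=2)
            continue
        ds = None
        try:
            arr = var.format("DS")
            if arr is not None:
                ds = np.asarray(arr, dtype=float).reshape(-1)
        except KeyError:
            pass
        if ds is None:
            gt = np.asarray(var.gt_types, dtype=float)  # 0,1,3 alt copies; 2=unknown
            ds = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        ds = np.where((ds < 0) | (ds > 2), np.nan, ds)
        gp = None
        try:
            arr = var.format("GP")
            if arr is not None:
                gp = np.asarray(arr, dtype=float)
                if gp.ndim == 2 and gp.shape[1] > 1:
                    gp = gp.max(axis=1)
                gp = gp.reshape(-1)
        except KeyError:
            pass
        if gp is None:
            gp = np.ones_like(ds)
        gp = np.where(np.isfinite(gp), gp, 1.0)
        r2 = var.INFO.get(r2_field)
        rows.append(
            dict(
                id=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=str(var.CHROM),
                pos=int(var.POS),
                ref=var.REF,
                alt=var.ALT[0],
                r2=float(r2) if r2 is not None else np.nan,
            )
        )
        dosages.append(ds)
        posts.append(gp)
    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    dosage = np.array(dosages, dtype=float).T if dosages else np.empty((len(donors), 0))
    post = np.array(posts, dtype=float).T if posts else np.empty((len(donors), 0))
    return GenotypeTable(donors=donors, snps=snps, dosage=dosage, call_posterior=post)
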