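"""Pseudobulk cis-eQTL mapping with a two-random-effect linear mixed model.

Per gene, donor-level expression y is modelled as

    y = X b + g_kin + g_depth + e,
    cov(y) = sigma2_g K + sigma2_d D + sigma2_e I,

with K the kinship (population-structure) covariance and D =
diag(1/n_i) a per-donor read-depth random effect (n_i = summed UMIs).
Variance components are estimated once per gene by REML under the null
(no genotype), each cis SNP is then tested by generalized least squares
with the null covariance held fixed, gene-level multiplicity is handled
by a min-p permutation scheme (donor labels of y permuted, preserving
cis LD), and study-wide multiplicity by Storey q-values or a
conditional-FDR variant stratifying on an external reference study.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats


@dataclass
class CisWindow:
    """Gene cis region: the gene body extended by ``flank`` bp each side."""

    gene: str
    chrom: str
    start: int
    end: int
    flank: int = 100_000

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass
class LmmFit:
    """Null-model variance components for one gene."""

    sigma2_g: float
    sigma2_d: float
    sigma2_e: float
    loglik: float
    converged: bool
    method: str = "reml"

    def __post_init__(self):
        for v in (self.sigma2_g, self.sigma2_d, self.sigma2_e):
            if v < 0:
                raise ValueError("variance components must be >= 0")

    def covariance(self, K: np.ndarray, reads: np.ndarray) -> np.ndarray:
        D = np.diag(1.0 / np.asarray(reads, dtype=float))
        n = len(reads)
        return self.sigma2_g * K + self.sigma2_d * D + self.sigma2_e * np.eye(n)


def cis_snps(window: CisWindow, snps: pd.DataFrame) -> pd.DataFrame:
    """SNPs within the boundary-inclusive cis window (same chromosome only)."""
    lo = window.start - window.flank
    hi = window.end + window.flank
    m = (snps["chrom"].astype(str) == str(window.chrom)) & (snps["pos"] >= lo) & (snps["pos"] <= hi)
    return snps.loc[m]


def _prepare_K(K: np.ndarray) -> np.ndarray:
    """Clip tiny negative eigenvalues so K is numerically PSD."""
    K = np.asarray(K, dtype=float)
    K = (K + K.T) / 2
    w = linalg.eigvalsh(K)
    if w.min() < -1e-8:
        warnings.warn("kinship matrix not PSD; clipping negative eigenvalues", stacklevel=2)
        w, V = linalg.eigh(K)
        K = (V * np.maximum(w, 0.0)) @ V.T
    return K


def _neg2_reml(log_gammas, y, X, K, Dd):
    """-2 x REML log-likelihood profiled over the residual scale.

    Parameterization: cov(y) = sigma2_e * (I + g_k K + g_d D) with
    gammas on log scale.
    """
    g_k, g_d = np.exp(log_gammas)
    n, p = X.shape
    V = np.eye(n) + g_k * K + g_d * np.diag(Dd)
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return np.inf
    logdet_V = 2.0 * np.log(np.diag(L)).sum()
    Xi = linalg.solve_triangular(L, X, lower=True)
    yi = linalg.solve_triangular(L, y, lower=True)
    XtX = Xi.T @ Xi
    beta = linalg.solve(XtX, Xi.T @ yi, assume_a="pos")
    r = yi - Xi @ beta
    rss = float(r @ r)
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    sign, logdet_XtX = np.linalg.slogdet(XtX)
    return (n - p) * np.log(sigma2) + logdet_V + logdet_XtX


def fit_null_lmm(
    y: np.ndarray,
    K: np.ndarray,
    reads: np.ndarray,
    covariates: np.ndarray | None = None,
) -> LmmFit:
    """REML fit of the two-variance-component null model for one gene.

    Optimizes the variance ratios (sigma2_g/sigma2_e, sigma2_d/sigma2_e)
    on the log scale with multiple starting points, profiling out the
    residual scale.  Falls back to OLS (all variance in the residual) if
    no start converges.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need >= 10 donors for the LMM")
    reads = np.asarray(reads, dtype=float)
    if (reads <= 0).any():
        raise ValueError("per-donor read totals must be > 0")
    K = _prepare_K(K)
    if K.shape != (n, n) or len(reads) != n:
        raise ValueError("K and reads must align with y")
    X = np.ones((n, 1))
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])
    Dd = 1.0 / reads

    # coarse multi-start grid on the log-ratio scale, then a local polish
    grid = [-8.0, -4.0, -1.0, 1.0, 3.0]
    start, start_val = None, np.inf
    for a in grid:
        for b in grid:
            v = _neg2_reml(np.array([a, b]), y, X, K, Dd)
            if v < start_val:
                start, start_val = np.array([a, b]), v
    best = optimize.minimize(
        _neg2_reml, start, args=(y, X, K, Dd),
        method="Nelder-Mead",
        options=dict(xatol=1e-3, fatol=1e-6, maxiter=300),
    )
    best_val = best.fun
    converged = np.isfinite(best_val)
    if not converged:
        s2 = float(np.var(y, ddof=1))
        return LmmFit(0.0, 0.0, s2, -np.inf, False, method="ols_fallback")

    g_k, g_d = np.exp(best.x)
    n_, p = X.shape
    V = np.eye(n) + g_k * K + g_d * np.diag(Dd)
    L = linalg.cholesky(V, lower=True)
    Xi = linalg.solve_triangular(L, X, lower=True)
    yi = linalg.solve_triangular(L, y, lower=True)
    beta = linalg.solve(Xi.T @ Xi, Xi.T @ yi, assume_a="pos")
    r = yi - Xi @ beta
    sigma2_e = float(r @ r) / (n_ - p)
    const = (n_ - p) * np.log(2 * np.pi)
    loglik = -0.5 * (best_val + const + (n_ - p))
    # tiny ratios are numerical zeros of the profile likelihood
    g_k = 0.0 if g_k < 1e-6 else g_k
    g_d = 0.0 if g_d < 1e-6 else g_d
    return LmmFit(
        sigma2_g=sigma2_e * g_k,
        sigma2_d=sigma2_e * g_d,
        sigma2_e=sigma2_e,
        loglik=loglik,
        converged=bool(best.success),
    )


def test_snp(
    y: np.ndarray,
    g_dosage: np.ndarray,
    fit: LmmFit,
    K: np.ndarray,
    reads: np.ndarray,
    covariates: np.ndarray | None = None,
) -> dict:
    """GLS association test of one SNP with the null covariance held fixed.

    Donors with missing dosage are dropped pairwise.  The whitened model
    is refit by least squares with the residual scale re-estimated, so
    the test reduces exactly to OLS when both variance components are
    zero.  Wald p against Normal(0, 1).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g_dosage, dtype=float)
    keep = ~np.isnan(g)
    y, g = y[keep], g[keep]
    K_s = np.asarray(K, dtype=float)[np.ix_(keep, keep)]
    reads_s = np.asarray(reads, dtype=float)[keep]
    if np.var(g) == 0:
        return dict(beta=np.nan, se=np.nan, p=np.nan, n=int(keep.sum()),
                    skipped="zero dosage variance")
    X = np.ones((len(y), 1))
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)[keep]])
    X = np.column_stack([X, g])
    Sigma = fit.covariance(K_s, reads_s)
    L = linalg.cholesky(Sigma + 1e-12 * np.eye(len(y)), lower=True)
    Xi = linalg.solve_triangular(L, X, lower=True)
    yi = linalg.solve_triangular(L, y, lower=True)
    XtX_inv = linalg.inv(Xi.T @ Xi)
    beta = XtX_inv @ (Xi.T @ yi)
    r = yi - Xi @ beta
    n, p = X.shape
    s2 = float(r @ r) / (n - p)
    se = float(np.sqrt(s2 * XtX_inv[-1, -1]))
    b = float(beta[-1])
    z = b / se
    return dict(beta=b, se=se, p=float(2 * stats.norm.sf(abs(z))), n=n, skipped=None)


def gene_level_permutation(
    y: np.ndarray,
    G: np.ndarray,
    fit: LmmFit,
    K: np.ndarray,
    reads: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    covariates: np.ndarray | None = None,
) -> float:
    """Gene-level empirical p-value from a min-p permutation scheme.

    The observed statistic is the minimum nominal p over cis SNPs; the
    null re-derives the same minimum with donor labels permuted (one
    permutation shared across SNPs, preserving LD among them).  The
    permutation happens after whitening by the fitted null covariance:
    the decorrelated donor residuals are exchangeable under the fitted
    model, whereas raw expression is not when kinship or depth variance
    is present.  Returns ``p_perm = (1 + #{null_min <= obs_min}) /
    (n_perm + 1)``.  Missing dosages are mean-imputed within SNP for
    this scan.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if G.shape[1] == 0:
        raise ValueError("need at least one testable cis SNP")
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean[None, :], G)

    n = len(y)
    Sigma = fit.covariance(np.asarray(K, dtype=float), np.asarray(reads, dtype=float))
    L = linalg.cholesky(Sigma + 1e-12 * np.eye(n), lower=True)
    X0 = np.ones((n, 1))
    if covariates is not None:
        X0 = np.column_stack([X0, np.asarray(covariates, dtype=float)])
    X0w = linalg.solve_triangular(L, X0, lower=True)
    Q, _ = np.linalg.qr(X0w)

    def whiten_project(M):
        Mw = linalg.solve_triangular(L, M, lower=True)
        return Mw - Q @ (Q.T @ Mw)

    Gw = whiten_project(G)
    g_norm = np.sqrt((Gw**2).sum(axis=0))
    ok = g_norm > 0
    if not ok.any():
        raise ValueError("all cis SNPs have zero variance after whitening")
    Gw = Gw[:, ok] / g_norm[ok]
    y0 = whiten_project(y[:, None])[:, 0]

    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = y0[rng.permutation(n)]
    # re-project permuted residuals so the fixed-effect space stays excluded
    perms -= Q @ (Q.T @ perms)
    Y = np.column_stack([y0, perms])
    y_norm = np.sqrt((Y**2).sum(axis=0))
    R = np.abs(Gw.T @ Y) / np.where(y_norm > 0, y_norm, np.inf)
    max_abs = R.max(axis=0)
    obs, null = max_abs[0], max_abs[1:]
    return float((1 + (null >= obs).sum()) / (n_perm + 1))


def storey_qvalues(p: np.ndarray, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single fixed lambda.

    ``pi0 = #{p > lambda} / (m (1 - lambda))`` capped at 1 (robust at
    small gene counts); q_i is the usual monotone step-up transform.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    pi0 = min(1.0, float((p > lambda_).sum()) / (m * (1 - lambda_)))
    pi0 = max(pi0, 1.0 / m)  # guard against pi0 = 0 with tiny m
    order = np.argsort(p)
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def conditional_fdr(
    p_perm: np.ndarray,
    reference_p: np.ndarray,
    alpha: float = 0.10,
    ref_threshold: float | None = None,
) -> pd.DataFrame:
    """Conditional FDR: Storey q-values within a reference-conditioned stratum.

    Genes with reference evidence (``reference_p`` below the threshold,
    default Bonferroni 0.05/#reference genes) form the conditioned
    stratum and receive Storey q-values among themselves; all remaining
    genes — including those absent from the reference (NaN) — are
    handled by the plain Storey branch.  Flags are set at q < alpha
    (FDR/cFDR controlled at 10% by default).
    """
    p_perm = np.asarray(p_perm, dtype=float)
    reference_p = np.asarray(reference_p, dtype=float)
    if len(p_perm) != len(reference_p):
        raise ValueError("p_perm and reference_p must align")
    has_ref = ~np.isnan(reference_p)
    if ref_threshold is None:
        n_ref = int(has_ref.sum())
        ref_threshold = 0.05 / n_ref if n_ref else 0.0
    conditioned = has_ref & (reference_p < ref_threshold)
    q = np.full(len(p_perm), np.nan)
    method = np.where(conditioned, "cfdr", "storey")
    if conditioned.any():
        q[conditioned] = storey_qvalues(p_perm[conditioned])
    if (~conditioned).any():
        q[~conditioned] = storey_qvalues(p_perm[~conditioned])
    return pd.DataFrame(dict(p_perm=p_perm, q=q, method=method, significant=q < alpha))


def replication_concordance(results_a: pd.DataFrame, results_b: pd.DataFrame) -> float | None:
    """Replication rate in an external study.

    Pairs are joined on (gene, snp) with allele harmonization (the
    external beta flips sign when ref/alt are swapped); a pair
    replicates iff the effect direction is concordant and the external
    p is nominally significant (p < 0.05).  Returns None when nothing
    joins.
    """
    a = results_a.copy()
    b = results_b.copy()
    merged = a.merge(b, on=["gene", "snp"], suffixes=("_a", "_b"))
    if {"ref_a", "alt_a", "ref_b", "alt_b"} <= set(merged.columns):
        same = (merged["ref_a"] == merged["ref_b"]) & (merged["alt_a"] == merged["alt_b"])
        flipped = (merged["ref_a"] == merged["alt_b"]) & (merged["alt_a"] == merged["ref_b"])
        merged = merged[same | flipped]
        merged.loc[flipped[same | flipped], "beta_b"] *= -1
    if merged.empty:
        return None
    replicated = (np.sign(merged["beta_a"]) == np.sign(merged["beta_b"])) & (merged["p_b"] < 0.05)
    return float(replicated.mean())


# ---------------------------------------------------------------------------
# per-cell-type scan driver
# ---------------------------------------------------------------------------

def map_eqtls(
    pb,
    geno,
    kinship,
    gene_windows: dict,
    maf_min: float = 0.10,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.10,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """cis-eQTL scan for one cell type's pseudobulk matrix.

    For each gene with >= 1 cis SNP passing the MAF filter: fit the null
    LMM, test every cis SNP by GLS, compute the gene-level permutation
    p, then correct across genes by Storey q-values (or conditional FDR
    when a reference with columns ``gene, p`` is supplied).  Returns the
    lead SNP row per gene.
    """
    from .genotype import minor_allele_frequency

    geno_s = geno.subset_donors(pb.donors)
    K = kinship.align(pb.donors)
    maf = np.array([minor_allele_frequency(geno_s.dosage[:, j]) for j in range(geno_s.n_snps)])
    testable = maf >= maf_min

    rows = []
    for gi, gene in enumerate(pb.genes):
        win = gene_windows.get(gene)
        if win is None:
            continue
        snps_cis = cis_snps(win, geno_s.snps)
        idx = [j for j in snps_cis.index if testable[j]]
        if not idx:
            continue
        y = pb.expr[:, gi]
        fit = fit_null_lmm(y, K, pb.total_reads)
        best = None
        for j in idx:
            res = test_snp(y, geno_s.dosage[:, j], fit, K, pb.total_reads)
            if res["skipped"]:
                continue
            if best is None or res["p"] < best[1]["p"]:
                best = (j, res)
        if best is None:
            continue
        j, res = best
        p_perm = gene_level_permutation(
            y, geno_s.dosage[:, idx], fit, K, pb.total_reads,
            n_perm=n_perm, seed=seed + gi,
        )
        rows.append(
            dict(
                cell_type=pb.cell_type, gene=gene,
                snp=geno_s.snps.loc[j, "id"], chrom=geno_s.snps.loc[j, "chrom"],
                pos=int(geno_s.snps.loc[j, "pos"]), beta=res["beta"], se=res["se"],
                p_nominal=res["p"], p_perm=p_perm, n_donors=res["n"],
            )
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if reference is not None:
        ref_p = out["gene"].map(reference.set_index("gene")["p"]).to_numpy(dtype=float)
        fdr = conditional_fdr(out["p_perm"].to_numpy(), ref_p, alpha=alpha)
        out["q_value"] = fdr["q"].to_numpy()
        out["method"] = fdr["method"].to_numpy()
        out["significant"] = fdr["significant"].to_numpy()
    else:
        out["q_value"] = storey_qvalues(out["p_perm"].to_numpy())
        out["method"] = "storey"
        out["significant"] = out["q_value"] < alpha
    return out
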