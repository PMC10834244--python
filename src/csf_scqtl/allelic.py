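"""Beta-binomial tests for allelic imbalance and transcript usage.

Allele-specific expression (ASE): per SNP and cell type, donor-level
(alt, total) UMI counts from heterozygous donors are fit by a
beta-binomial regression with a logit-scale intercept and a shared
overdispersion; testing "mean allele fraction = 0.5" is testing that
the intercept is 0 (Wald).  Transcript usage: per-donor two-isoform
counts are fit with a genotype-dosage slope on the logit of the
long-isoform proportion; the Wald p on the slope tests for a genetic
effect on usage.  Both use the repo-wide (mean, overdispersion)
beta-binomial parameterization.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from ._betabinom import betabinom_logpmf


@dataclass
class BetaBinFit:
    """Beta-binomial regression fit on the logit scale."""

    coef: np.ndarray  # (b0,) or (b0, b1)
    se: np.ndarray
    phi: float
    wald_p: np.ndarray
    loglik: float
    converged: bool
    n_donors: int
    method: str = "betabinomial_ml"
    fitted_proportions: dict | None = None
    skipped: str | None = None

    def __post_init__(self):
        if self.phi < 0:
            raise ValueError("phi must be >= 0")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def betabin_loglik(k, n, X, coef, phi):
    """Log-likelihood of logit(mu_i) = X_i . coef with shared overdispersion."""
    mu = _expit(X @ np.asarray(coef))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(betabinom_logpmf(k, n, mu, phi).sum())


def _nll(params, k, n, X):
    coef = params[:-1]
    phi = _expit(params[-1])
    mu = np.clip(_expit(X @ coef), 1e-12, 1 - 1e-12)
    ll = betabinom_logpmf(k, n, mu, phi)
    return -float(np.sum(ll))


def _numeric_hessian(f, x, eps=1e-4):
    x = np.asarray(x, dtype=float)
    m = len(x)
    H = np.empty((m, m))
    f0 = f(x)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = eps
            ej = np.zeros(m); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def _fit_betabin(k, n, X) -> tuple:
    """ML fit of the (coef, phi) beta-binomial regression.

    Optimization runs on the unconstrained scale (coef, logit phi) with
    multiple starts: the pooled binomial estimate with phi near 0 and
    with phi = 0.1.  Returns (coef, se, phi, loglik, converged); the se
    come from the observed information (numerical Hessian).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    pooled = np.clip((k.sum() + 0.5) / (n.sum() + 1.0), 1e-6, 1 - 1e-6)
    b0 = np.log(pooled / (1 - pooled))
    starts = []
    for phi0 in (0.02, 0.1):
        s = np.zeros(p + 1)
        s[0] = b0
        s[-1] = np.log(phi0 / (1 - phi0))
        starts.append(s)
    best = None
    for s in starts:
        res = optimize.minimize(_nll, s, args=(k, n, X), method="Nelder-Mead",
                                options=dict(xatol=1e-7, fatol=1e-9, maxiter=2000))
        if best is None or res.fun < best.fun:
            best = res
    coef = best.x[:-1]
    phi = float(_expit(best.x[-1]))
    converged = bool(best.success)

    def _se_from(hess, upto):
        try:
            with np.errstate(invalid="ignore"):
                s = np.sqrt(np.diag(np.linalg.inv(hess))[:upto])
        except np.linalg.LinAlgError:
            return None
        if np.all(np.isfinite(s)) and np.all(s > 0):
            return s
        return None

    se = _se_from(_numeric_hessian(lambda x: _nll(x, k, n, X), best.x), p)
    if se is None:
        # phi at the boundary makes the joint information singular; condition
        # on the fitted phi and use the coefficient-block information
        eta = best.x[-1]
        se = _se_from(
            _numeric_hessian(lambda b: _nll(np.append(b, eta), k, n, X), coef), p
        )
    if se is None:
        converged = False
        se = np.full(p, np.nan)
    return coef, se, phi, -float(best.fun), converged


def _wald_p(coef, se, n_obs):
    """Two-sided Wald p-values with a t reference.

    The reference uses the regression's residual degrees of freedom
    (donors minus coefficients); at the donor counts of pseudobulk ASE
    and usage tests the normal reference is measurably anti-conservative
    and the t reference restores nominal calibration.
    """
    coef = np.asarray(coef, dtype=float)
    dfree = max(int(n_obs) - len(coef), 1)
    return 2 * stats.t.sf(np.abs(coef / np.asarray(se, dtype=float)), df=dfree)


def _binomial_glm_fallback(k, n, X):
    """Binomial GLM fallback reported when the beta-binomial ML fails."""
    import statsmodels.api as sm

    model = sm.GLM(np.column_stack([k, n - k]), X, family=sm.families.Binomial())
    fit = model.fit()
    return np.asarray(fit.params), np.asarray(fit.bse), float(fit.llf)


def betabin_ase_test(
    alt: np.ndarray,
    total: np.ndarray,
    min_donors: int = 2,
    min_total: int = 5,
) -> BetaBinFit:
    """Test allelic balance: is the mean allele fraction 0.5?

    Fits logit(mu) = b0 with shared overdispersion across donors and
    returns the Wald p for b0 = 0.  Donors with zero total are dropped;
    the test is skipped below the donor/UMI thresholds.
    """
    alt = np.asarray(alt, dtype=float)
    total = np.asarray(total, dtype=float)
    keep = total > 0
    alt, total = alt[keep], total[keep]
    if len(alt) < min_donors or total.sum() < min_total:
        return BetaBinFit(np.array([np.nan]), np.array([np.nan]), 0.0,
                          np.array([np.nan]), np.nan, False, len(alt),
                          skipped=f"fewer than {min_donors} donors or {min_total} pooled UMIs")
    X = np.ones((len(alt), 1))
    coef, se, phi, ll, conv = _fit_betabin(alt, total, X)
    method = "betabinomial_ml"
    if not conv:
        coef, se, ll = _binomial_glm_fallback(alt, total, X)
        phi = 0.0
        method = "binomial_glm_fallback"
    p = _wald_p(coef, se, n_obs=len(alt))
    return BetaBinFit(coef, se, phi, p, ll, conv, len(alt), method=method,
                      fitted_proportions={"mean_af": float(_expit(coef[0]))})


def betabin_usage_test(
    long_counts: np.ndarray,
    short_counts: np.ndarray,
    dosage: np.ndarray,
) -> BetaBinFit:
    """Test for a genotype effect on two-isoform usage.

    Fits logit(psi) = b0 + b1 * dosage on per-donor (long, long+short)
    counts; the Wald p on b1 tests the genetic effect.  Also reports the
    pooled and fitted long-isoform proportion per genotype group.
    Undefined (skipped) with a single genotype group.
    """
    long_counts = np.asarray(long_counts, dtype=float)
    short_counts = np.asarray(short_counts, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    total = long_counts + short_counts
    keep = total > 0
    long_counts, total, dosage = long_counts[keep], total[keep], dosage[keep]
    groups = np.unique(dosage)
    if len(groups) < 2:
        return BetaBinFit(np.array([np.nan, np.nan]), np.array([np.nan, np.nan]), 0.0,
                          np.array([np.nan, np.nan]), np.nan, False, len(total),
                          skipped="single genotype group")
    X = np.column_stack([np.ones(len(total)), dosage])
    coef, se, phi, ll, conv = _fit_betabin(long_counts, total, X)
    method = "betabinomial_ml"
    if not conv:
        coef, se, ll = _binomial_glm_fallback(long_counts, total, X)
        phi = 0.0
        method = "binomial_glm_fallback"
    p = _wald_p(coef, se, n_obs=len(total))
    props = {}
    for g in (0.0, 1.0, 2.0):
        m = dosage == g
        props[f"pooled_psi_{int(g)}"] = float(long_counts[m].sum() / total[m].sum()) if m.any() else np.nan
        props[f"fitted_psi_{int(g)}"] = float(_expit(coef[0] + coef[1] * g))
    return BetaBinFit(coef, se, phi, p, ll, conv, len(total), method=method,
                      fitted_proportions=props)


def ase_fdr_flags(p: np.ndarray, thresholds: tuple = (0.01, 0.0001)) -> pd.DataFrame:
    """Benjamini-Hochberg FDR with two-level significance flags.

    One asterisk at FDR < 0.01, two at FDR < 0.0001, matching the
    reporting convention for ASE heatmaps.
    """
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return pd.DataFrame(columns=["p", "fdr", "flag1", "flag2"])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        dict(p=p, fdr=fdr, flag1=fdr < thresholds[0], flag2=fdr < thresholds[1])
    )


def select_informative_snp(candidates: pd.DataFrame) -> str | None:
    """Pick the single ASE SNP to test for a gene.

    ``candidates`` has one row per (snp, donor) with columns ``snp, pos,
    is_het, total_umis``.  The chosen SNP maximizes the number of donors
    that are heterozygous AND have at least one covering UMI; ties break
    to the smallest genomic position.  Returns None when no SNP is
    informative in any donor.
    """
    df = candidates.copy()
    df["informative"] = df["is_het"].astype(bool) & (df["total_umis"] > 0)
    counts = (
        df.groupby("snp")
        .agg(n_informative=("informative", "sum"), pos=("pos", "first"))
        .reset_index()
    )
    counts = counts[counts["n_informative"] > 0]
    if counts.empty:
        return None
    counts = counts.sort_values(["n_informative", "pos"], ascending=[False, True])
    return str(counts.iloc[0]["snp"])


def ase_scan(allele_counts: pd.DataFrame, min_donors: int = 2, min_total: int = 5) -> pd.DataFrame:
    """Run the ASE test per (snp, gene, cell type) over a pseudobulk allele table.

    Expects columns donor, snp, gene, cell_type, ref_count, alt_count
    (heterozygous donors only); FDR flags are computed per cell type.
    """
    rows = []
    for (snp, gene, ct), grp in allele_counts.groupby(["snp", "gene", "cell_type"]):
        agg = grp.groupby("donor")[["ref_count", "alt_count"]].sum()
        total = (agg["ref_count"] + agg["alt_count"]).to_numpy()
        fit = betabin_ase_test(agg["alt_count"].to_numpy(), total,
                               min_donors=min_donors, min_total=min_total)
        if fit.skipped:
            continue
        rows.append(
            dict(snp=snp, gene=gene, cell_type=ct, b0=fit.coef[0], se=fit.se[0],
                 phi=fit.phi, mean_af=fit.fitted_proportions["mean_af"],
                 p=fit.wald_p[0], n_donors=fit.n_donors, method=fit.method)
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = np.nan
    out["flag1"] = False
    out["flag2"] = False
    for ct, grp in out.groupby("cell_type"):
        flags = ase_fdr_flags(grp["p"].to_numpy())
        out.loc[grp.index, ["fdr", "flag1", "flag2"]] = flags[["fdr", "flag1", "flag2"]].to_numpy()
    return out


def usage_scan(isoform_counts: pd.DataFrame) -> pd.DataFrame:
    """Run the usage-QTL test per (gene, snp, cell type) on per-cell isoform counts.

    Cells are aggregated to donor level (summed long/short counts)
    before fitting, mirroring the pseudobulk treatment of ASE.
    """
    rows = []
    for (gene, snp, ct), grp in isoform_counts.groupby(["gene", "snp", "cell_type"]):
        agg = grp.groupby("donor").agg(
            long_count=("long_count", "sum"),
            short_count=("short_count", "sum"),
            dosage=("dosage", "first"),
        )
        fit = betabin_usage_test(
            agg["long_count"].to_numpy(), agg["short_count"].to_numpy(), agg["dosage"].to_numpy()
        )
        if fit.skipped:
            continue
        row = dict(gene=gene, snp=snp, cell_type=ct, b0=fit.coef[0], b1=fit.coef[1],
                   se_b1=fit.se[1], phi=fit.phi, p=fit.wald_p[1], n_donors=fit.n_donors,
                   method=fit.method)
        row.update(fit.fitted_proportions)
        rows.append(row)
    return pd.DataFrame(rows)
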