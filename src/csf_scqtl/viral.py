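"""Viral-presence statistics on a cell-by-virus UMI matrix.

Donor-level presence is "at least one UMI across any cell"; viruses are
kept for testing when prevalent in more than 5% of either the MS or the
non-MS cohort.  Two models are provided: a per-virus logistic
regression ``Virus_present ~ is_MS + total_UMIs + intercept`` (BH FDR
at 10% across tested viruses), and a donor-level linear model
``viral_proportion ~ is_MS + total_UMIs_log + total_cells_log +
intercept`` where the proportion is the fraction of a donor's cells
carrying at least one viral UMI of any virus.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def donor_presence(
    virus_counts: pd.DataFrame,
    cell_meta: pd.DataFrame,
    prevalence_min: float = 0.05,
) -> dict:
    """Donor x virus presence table, per-cohort prevalence and the test set.

    ``virus_counts`` is cell x virus UMIs indexed by cell;
    ``cell_meta`` (indexed by cell) must carry ``donor`` and ``group``.
    A virus is testable when its prevalence strictly exceeds
    ``prevalence_min`` in either the MS or the non-MS cohort.
    """
    donors = cell_meta["donor"]
    donor_sum = virus_counts.groupby(donors.to_numpy()).sum()
    presence = donor_sum >= 1
    donor_group = cell_meta.groupby("donor")["group"].first().loc[presence.index]
    is_ms = donor_group == "MS"
    prev = pd.DataFrame(
        dict(
            prevalence_ms=presence.loc[is_ms.to_numpy()].mean(axis=0),
            prevalence_non_ms=presence.loc[~is_ms.to_numpy()].mean(axis=0),
        )
    )
    prev["testable"] = (prev["prevalence_ms"] > prevalence_min) | (
        prev["prevalence_non_ms"] > prevalence_min
    )
    return dict(presence=presence, prevalence=prev, is_ms=is_ms)


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth-penalized logistic regression (Jeffreys-prior score adjustment).

    Used as the fallback under (quasi-)separation, where plain ML
    estimates diverge; the half-weight hat-diagonal adjustment keeps the
    estimates finite.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        W = np.clip(w, 1e-10, None)
        XtW = X.T * W
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        # hat diagonal of the weighted design
        H = (X @ info_inv * (X.T * W).T).sum(axis=1)
        score = X.T @ (y - mu + H * (0.5 - mu))
        step = info_inv @ score
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    info = (X.T * w) @ X
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


def donor_prevalence_test(
    presence: pd.DataFrame,
    is_ms: pd.Series,
    total_umis: pd.Series,
    testable: pd.Series | None = None,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Per-virus logistic regression Virus_present ~ is_MS + total_UMIs + intercept.

    Viruses without both present and absent donors are skipped (no
    variation).  Under separation the Firth-penalized fit is reported
    with a flag.  BH FDR at 10% across tested viruses.
    """
    import statsmodels.api as sm

    idx = presence.index
    x_ms = is_ms.loc[idx].to_numpy(dtype=float)
    x_umi = total_umis.loc[idx].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(idx)), x_ms, x_umi])
    rows = []
    viruses = presence.columns if testable is None else presence.columns[testable.loc[presence.columns]]
    for v in viruses:
        y = presence[v].to_numpy(dtype=float)
        if y.min() == y.max():
            rows.append(dict(virus=v, coef_is_ms=np.nan, se=np.nan, p=np.nan,
                             method="skipped_no_variation"))
            continue
        method = "logistic_ml"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                coef, se = fit.params, fit.bse
                separated = (not np.all(np.isfinite(se))) or np.any(np.abs(coef) > 15)
            except Exception:
                separated = True
        if separated:
            coef, se = _firth_logistic(X, y)
            method = "firth_penalized"
        z = coef[1] / se[1]
        rows.append(dict(virus=v, coef_is_ms=float(coef[1]), se=float(se[1]),
                         p=float(2 * stats.norm.sf(abs(z))), method=method))
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr
    return out


def cell_level_test(virus_counts: pd.DataFrame, cell_meta: pd.DataFrame) -> dict:
    """Donor-level linear model of the viral cell proportion.

    ``viral_proportion`` is the fraction of the donor's cells with at
    least one viral UMI (any virus); regressed on is_MS with log total
    transcriptome UMIs and log cell count as covariates (OLS, Wald p on
    is_MS).  Degenerate all-zero proportions return coef 0, p 1,
    flagged.
    """
    cell_has_virus = (virus_counts.sum(axis=1) >= 1).astype(float)
    donors = cell_meta["donor"]
    prop = cell_has_virus.groupby(donors.to_numpy()).mean()
    n_cells = donors.value_counts().loc[prop.index]
    if "total_umis" in cell_meta.columns:
        total_umis = cell_meta.groupby("donor")["total_umis"].sum().loc[prop.index]
    else:
        total_umis = virus_counts.sum(axis=1).groupby(donors.to_numpy()).sum().loc[prop.index] + n_cells
    group = cell_meta.groupby("donor")["group"].first().loc[prop.index]
    is_ms = (group == "MS").to_numpy(dtype=float)
    if is_ms.sum() < 2 or (1 - is_ms).sum() < 2:
        raise ValueError("need >= 2 donors per group")
    y = prop.to_numpy()
    if np.allclose(y, 0):
        return dict(coef_is_ms=0.0, se=np.nan, p=1.0, degenerate=True, n_donors=len(y))
    import statsmodels.api as sm

    X = np.column_stack(
        [np.ones(len(y)), is_ms, np.log(total_umis.to_numpy(dtype=float)),
         np.log(n_cells.to_numpy(dtype=float))]
    )
    fit = sm.OLS(y, X).fit()
    return dict(
        coef_is_ms=float(fit.params[1]), se=float(fit.bse[1]), p=float(fit.pvalues[1]),
        degenerate=False, n_donors=len(y), df_resid=int(fit.df_resid),
    )
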