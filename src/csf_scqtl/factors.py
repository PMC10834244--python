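"""Downstream statistics on a fitted factor model.

The factorization itself (e.g. MOFA+) is consumed, not fit: the module
takes cell x factor values Z and gene x factor weights W and provides
the analyses layered on top — per-cell-type variance-explained
filtering, donor-level permutation tests for disease association,
transcription-factor regulon enrichment via the matrix product W^T T
against a random-gene-set null, and a competitive |weight| gene-set
test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class FactorModel:
    """Factor values Z (cell x factor), weights W (gene x factor), cell metadata.

    ``cell_meta`` is indexed by cell and must carry ``donor``, ``group``
    and ``cell_type`` columns.  The factor count must be consistent
    between Z and W (a 30-factor model is the conventional setting).
    """

    Z: pd.DataFrame
    W: pd.DataFrame
    cell_meta: pd.DataFrame
    expression: pd.DataFrame | None = None  # cell x gene matrix the model was fit to

    def __post_init__(self):
        if self.Z.shape[1] != self.W.shape[1]:
            raise ValueError("factor count mismatch between Z and W")
        if not np.isfinite(self.Z.to_numpy()).all() or not np.isfinite(self.W.to_numpy()).all():
            raise ValueError("non-finite entries in factor model")
        missing = {"donor", "group", "cell_type"} - set(self.cell_meta.columns)
        if missing:
            raise ValueError(f"cell_meta missing columns: {sorted(missing)}")

    @property
    def factors(self) -> list:
        return list(self.Z.columns)


def variance_explained(
    model: FactorModel,
    cell_type: str,
    expression: pd.DataFrame | np.ndarray | None = None,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-factor R^2 on the centered expression of one cell type.

    ``R^2_f = 1 - ||Y - z_f w_f^T||^2 / ||Y||^2`` where Y is the
    (column-centered) cell x gene expression the model was fit to,
    restricted to cells of ``cell_type``.  Factors with R^2 >= threshold
    are flagged as retained (the 1%-of-variance filter).
    """
    if expression is None:
        expression = model.expression
    if expression is None:
        raise ValueError("variance_explained requires the expression matrix the model was fit to")
    mask = (model.cell_meta["cell_type"] == cell_type).to_numpy()
    if mask.sum() < 2:
        raise ValueError(f"need >=2 cells of type {cell_type}")
    Y = np.asarray(expression, dtype=float)[mask]
    Y = Y - Y.mean(axis=0, keepdims=True)
    ss_tot = float((Y**2).sum())
    # center factor values within the subset to match the centered expression
    Zc = model.Z.to_numpy()[mask]
    Zc = Zc - Zc.mean(axis=0, keepdims=True)
    W = model.W.to_numpy()
    rows = []
    for f, name in enumerate(model.factors):
        resid = Y - np.outer(Zc[:, f], W[:, f])
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
        rows.append(dict(factor=name, cell_type=cell_type, r2=r2, retained=r2 >= threshold))
    return pd.DataFrame(rows)


def factor_disease_association(
    model: FactorModel,
    cell_type: str,
    factor: str,
    groups: tuple = ("MS", "IIH"),
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Donor-level permutation test of a factor's association with disease.

    Factor values are averaged per donor over that donor's cells of the
    cell type; the effect is the linear-regression coefficient of the
    donor mean on the case indicator, and the empirical p-value comes
    from permuting donor group labels: p = (1 + #{|effect*| >= |effect|})
    / (n_perm + 1).
    """
    case, control = groups
    meta = model.cell_meta
    mask = (meta["cell_type"] == cell_type) & meta["group"].isin(groups)
    sub = meta.loc[mask]
    vals = model.Z.loc[sub.index, factor]
    donor_mean = vals.groupby(sub["donor"]).mean()
    donor_group = sub.groupby("donor")["group"].first().loc[donor_mean.index]
    is_case = (donor_group == case).to_numpy().astype(float)
    if is_case.sum() < 3 or (1 - is_case).sum() < 3:
        return dict(factor=factor, cell_type=cell_type, effect=np.nan, p=np.nan, skipped=True)
    y = donor_mean.to_numpy()

    def coef(lbl):
        # slope of y ~ 1 + lbl
        x = lbl - lbl.mean()
        return float(x @ (y - y.mean()) / (x @ x))

    obs = coef(is_case)
    rng = np.random.default_rng(seed)
    exceed = 0
    lbl = is_case.copy()
    for _ in range(n_perm):
        rng.shuffle(lbl)
        if abs(coef(lbl)) >= abs(obs):
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return dict(
        factor=factor, cell_type=cell_type, effect=obs, p=p,
        n_case=int(is_case.sum()), n_control=int((1 - is_case).sum()), skipped=False,
    )


def factor_disease_scan(
    model: FactorModel,
    expression_by_type: dict | None = None,
    groups: tuple = ("MS", "IIH"),
    var_threshold: float = 0.01,
    fdr: float = 0.10,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Variance-explained filter then disease association with BH FDR.

    ``expression_by_type`` maps cell type -> expression matrix aligned
    to the model's cells (default: the model's own fit matrix for every
    type).  Factor-cell-type pairs explaining at least ``var_threshold``
    of variance are tested; BH FDR at 10% flags the associated pairs.
    """
    if expression_by_type is None:
        types = sorted(model.cell_meta["cell_type"].unique())
        expression_by_type = {ct: model.expression for ct in types}
    tested = []
    for i, (ct, Y) in enumerate(expression_by_type.items()):
        ve = variance_explained(model, ct, Y, threshold=var_threshold)
        for _, row in ve.loc[ve["retained"]].iterrows():
            res = factor_disease_association(
                model, ct, row["factor"], groups=groups, n_perm=n_perm, seed=seed + i
            )
            res["r2"] = row["r2"]
            tested.append(res)
    out = pd.DataFrame(tested)
    if len(out):
        ok = out["p"].notna()
        out["fdr"] = np.nan
        if ok.any():
            out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["significant"] = out["fdr"] < fdr
    return out


def regulon_enrichment(
    W: pd.DataFrame,
    T: pd.DataFrame,
    n_samples: int = 10_000,
    seed: int = 0,
    two_sided: bool = True,
    min_targets: int = 3,
    aggregate: str = "sum",
) -> pd.DataFrame:
    """Regulon enrichment of factor weights against a random-gene-set null.

    The score matrix is the product S = W^T T: the aggregated factor
    weight over each transcription factor's targets.  For each TF with k
    targets, k genes are drawn uniformly without replacement from the
    shared gene universe ``n_samples`` times and the aggregate
    recomputed, giving an empirical p-value with floor 1/(n_samples+1).
    """
    universe = W.index.intersection(T.index)
    if len(universe) == 0:
        raise ValueError("empty gene universe between weights and regulons")
    Wm = W.loc[universe].to_numpy(dtype=float)
    Tm = T.loc[universe].to_numpy(dtype=float)
    n_genes, n_factors = Wm.shape
    sizes = Tm.sum(axis=0).astype(int)
    keep = sizes >= min_targets
    tfs = [t for t, k in zip(T.columns, keep) if k]
    S = Wm.T @ Tm[:, keep]  # factor x TF aggregated weights
    if aggregate == "mean":
        S = S / sizes[keep]
    rng = np.random.default_rng(seed)
    rows = []
    for ti, tf in enumerate(tfs):
        k = int(sizes[keep][ti])
        idx = np.empty((n_samples, k), dtype=np.intp)
        for s in range(n_samples):
            idx[s] = rng.choice(n_genes, size=k, replace=False)
        null = Wm[idx].sum(axis=1)  # n_samples x n_factors
        if aggregate == "mean":
            null = null / k
        for fi, fac in enumerate(W.columns):
            obs = S[fi, ti]
            # tolerance so a null draw recomposing the observed set counts
            # as an exceedance despite summation-order rounding
            tol = 1e-9 * max(1.0, abs(obs))
            if two_sided:
                exceed = int((np.abs(null[:, fi]) >= abs(obs) - tol).sum())
            else:
                exceed = int((null[:, fi] >= obs - tol).sum())
            rows.append(
                dict(factor=fac, tf=tf, n_targets=k, score=float(obs),
                     p=(1 + exceed) / (n_samples + 1))
            )
    return pd.DataFrame(rows)


def gsea_abs_weights(
    W: pd.DataFrame, gene_sets: dict, factor: str, min_overlap: int = 3
) -> pd.DataFrame:
    """Competitive rank-sum test of |factor weight| for members vs non-members.

    Genes are weighted by the absolute value of their factor weight; for
    each set, a Mann-Whitney U compares member against non-member
    |weights|, BH-corrected across sets.  Sets overlapping the universe
    in fewer than ``min_overlap`` genes, or covering it entirely, are
    skipped (no contrast).
    """
    w = W[factor].abs()
    rows = []
    for name, members in gene_sets.items():
        inset = w.index.isin(set(members))
        n_in = int(inset.sum())
        if n_in < min_overlap or n_in == len(w):
            rows.append(dict(gene_set=name, factor=factor, n_overlap=n_in, stat=np.nan,
                             p=np.nan, skipped=True))
            continue
        stat, p = stats.mannwhitneyu(w[inset], w[~inset], alternative="two-sided")
        rows.append(dict(gene_set=name, factor=factor, n_overlap=n_in, stat=float(stat),
                         p=float(p), skipped=False))
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out
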