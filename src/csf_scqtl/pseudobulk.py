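"""Single-cell normalization and donor-level (pseudobulk) aggregation.

Cells are normalized (negative-binomial Pearson residuals by default,
log-CP10K as a fallback) and mean-aggregated to donor level within a
cell type, applying the inclusion filters used for pseudobulk eQTL
mapping: donors need at least two cells of the type, and genes must be
detected (non-zero raw expression) in at least 10% of the retained
donors.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class PseudobulkMatrix:
    """Donor x gene mean normalized expression for one cell type.

    ``n_cells`` and ``total_reads`` are per-donor: the cell count behind
    each donor mean and the summed raw UMIs (the ``n`` entering the
    1/n read-depth random effect downstream).
    """

    cell_type: str
    donors: list
    genes: list
    expr: np.ndarray
    n_cells: np.ndarray
    total_reads: np.ndarray

    def __post_init__(self):
        self.expr = np.asarray(self.expr, dtype=float)
        if not np.isfinite(self.expr).all():
            raise ValueError("non-finite pseudobulk expression")
        if len(set(self.donors)) != len(self.donors) or len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate donor or gene identifiers")
        if (np.asarray(self.n_cells) < 2).any():
            raise ValueError("pseudobulk donors must have >= 2 cells")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expr, index=self.donors, columns=self.genes)


def _dense(counts) -> np.ndarray:
    if sparse.issparse(counts):
        return np.asarray(counts.todense(), dtype=float)
    return np.asarray(counts, dtype=float)


def _running_median(x: np.ndarray, order: np.ndarray, window: int = 51) -> np.ndarray:
    """Median smooth of x over a precomputed ordering (regularization)."""
    xs = x[order]
    half = window // 2
    out = np.empty_like(xs)
    for i in range(len(xs)):
        lo, hi = max(0, i - half), min(len(xs), i + half + 1)
        out[i] = np.median(xs[lo:hi])
    smoothed = np.empty_like(x)
    smoothed[order] = out
    return smoothed


def normalize_cells(counts, method: str = "pearson_nb", clip: float | None = None) -> np.ndarray:
    """Normalize a cell x gene count matrix.

    ``pearson_nb`` (default): per-gene negative-binomial Pearson
    residuals.  The expected count is ``depth_i * p_g`` (a log-depth
    offset model), the per-gene dispersion is a moment estimate
    regularized by a running median over genes ordered by log mean
    expression, and residuals are clipped at +/- sqrt(n_cells).

    ``log_cp10k``: log1p of depth-normalized counts scaled to 10^4.
    """
    X = _dense(counts)
    if (X < 0).any() or not np.allclose(X, np.rint(X)):
        raise ValueError("counts must be non-negative integers")
    n_cells, n_genes = X.shape
    depth = X.sum(axis=1)
    if method == "log_cp10k":
        safe = np.where(depth > 0, depth, 1.0)
        return np.log1p(X / safe[:, None] * 1e4)
    if method != "pearson_nb":
        raise ValueError(f"unknown normalization method: {method}")

    total = depth.sum()
    p_g = X.sum(axis=0) / total if total > 0 else np.zeros(n_genes)
    mu = depth[:, None] * p_g[None, :]

    gene_mean = X.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        # moment estimator of NB dispersion alpha in var = mu + alpha mu^2
        num = ((X - mu) ** 2 - mu).sum(axis=0)
        den = (mu**2).sum(axis=0)
        alpha = np.where(den > 0, np.maximum(num / den, 0.0), 0.0)
    expressed = gene_mean > 0
    if expressed.sum() > 2:
        order = np.argsort(np.log(gene_mean[expressed]))
        alpha_reg = alpha.copy()
        alpha_reg[expressed] = _running_median(alpha[expressed], order)
    else:
        alpha_reg = alpha

    var = mu + alpha_reg[None, :] * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.where(var > 0, (X - mu) / np.sqrt(var), 0.0)
    limit = np.sqrt(n_cells) if clip is None else clip
    return np.clip(resid, -limit, limit)


def aggregate_to_donor(
    normed: np.ndarray,
    counts,
    cell_meta: pd.DataFrame,
    cell_type: str,
    genes=None,
    min_cells: int = 2,
    min_donor_frac: float = 0.10,
) -> PseudobulkMatrix:
    """Mean-aggregate normalized cells to donor level for one cell type.

    Donors with fewer than ``min_cells`` cells of the type are dropped;
    genes with non-zero raw expression in fewer than ``min_donor_frac``
    of the retained donors are dropped (applied after the donor filter,
    per cell type).  ``total_reads`` sums raw UMIs per retained donor.
    """
    raw = _dense(counts)
    normed = np.asarray(normed, dtype=float)
    if normed.shape[0] != len(cell_meta) or raw.shape[0] != len(cell_meta):
        raise ValueError("cell_meta rows must match count/normalized matrix rows")
    if cell_meta[["donor", "cell_type"]].isna().any().any():
        raise ValueError("cell -> donor and cell -> type assignments must be total")
    mask = (cell_meta["cell_type"] == cell_type).to_numpy()
    donors_all = cell_meta["donor"].to_numpy()[mask]
    sub_norm, sub_raw = normed[mask], raw[mask]

    order = pd.unique(donors_all)
    keep_donors, expr_rows, ncell, reads, raw_rows = [], [], [], [], []
    for d in order:
        rows = donors_all == d
        if rows.sum() < min_cells:
            continue
        keep_donors.append(d)
        expr_rows.append(sub_norm[rows].mean(axis=0))
        raw_rows.append(sub_raw[rows].sum(axis=0))
        ncell.append(int(rows.sum()))
        reads.append(float(sub_raw[rows].sum()))
    if not keep_donors:
        raise ValueError(f"no donor has >= {min_cells} cells of type {cell_type}")

    expr = np.vstack(expr_rows)
    raw_pb = np.vstack(raw_rows)
    detected = (raw_pb > 0).mean(axis=0)
    gene_keep = detected >= min_donor_frac
    gene_ids = list(genes) if genes is not None else [f"g{j}" for j in range(expr.shape[1])]
    return PseudobulkMatrix(
        cell_type=cell_type,
        donors=list(keep_donors),
        genes=[g for g, k in zip(gene_ids, gene_keep) if k],
        expr=expr[:, gene_keep],
        n_cells=np.array(ncell),
        total_reads=np.array(reads),
    )


def align_to_genotyped(pb: PseudobulkMatrix, genotyped_donors) -> PseudobulkMatrix:
    """Inner-join pseudobulk donors with the genotyped donor set."""
    keep = [i for i, d in enumerate(pb.donors) if d in set(genotyped_donors)]
    dropped = len(pb.donors) - len(keep)
    if dropped:
        warnings.warn(f"{dropped} pseudobulk donors without genotypes excluded", stacklevel=2)
    return PseudobulkMatrix(
        cell_type=pb.cell_type,
        donors=[pb.donors[i] for i in keep],
        genes=pb.genes,
        expr=pb.expr[keep],
        n_cells=pb.n_cells[keep],
        total_reads=pb.total_reads[keep],
    )
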