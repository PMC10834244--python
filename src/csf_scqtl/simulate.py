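"""Synthetic data generator for the full analysis pipeline.

Emulates the inputs of a CSF single-cell eQTL study: ~80 donors in four
disease groups (MS, OIND, NIND, IIH), LD-structured biallelic SNP
dosages, negative-binomial UMI counts with donor random effects and
planted cis-eQTLs, beta-binomial allelic imbalance at heterozygous
sites, genotype-dependent two-isoform usage, a factor model with
planted regulon loading shifts, and a sparse cell-by-virus UMI matrix
with a disease-group effect.  All planted effects are recorded in a
GroundTruth object so downstream modules can be tested for recovery.

LD is generated through a Gaussian copula: haplotypes share a per-block
latent factor with loading sqrt(ld_rho), and alleles are the latent
value thresholded at the allele-frequency quantile, which controls the
pairwise dosage correlation without an external LD reference.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from ._betabinom import betabinom_rvs
from .genotype import SNP_COLUMNS, GenotypeTable, hard_calls
from .factors import FactorModel

SNP_SPACING = 5_000  # bp between adjacent simulated SNPs
GENE_LENGTH = 20_000  # bp per simulated gene body


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class PlantedEqtl:
    gene: int
    snp: int
    beta: float
    cell_type: str | None = None  # None -> first cell type


@dataclass
class PlantedAse:
    snp: int
    mean_af: float
    phi: float


@dataclass
class PlantedUsageQtl:
    gene: int
    snp: int
    psi: tuple  # long-isoform proportion per dosage (0, 1, 2)


@dataclass
class PlantedRegulon:
    factor: int
    tf: int
    loading_shift: float


@dataclass
class PlantedFactorDisease:
    factor: int
    cell_type: str
    donor_shift: float


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study's scale: 81 donors (33 MS, 48 split over
    OIND/NIND/IIH), 3 cell types, up to 200 cells per donor, a 30-factor
    model, and planted effects at the sizes the analyses are designed to
    detect (eQTL beta 0.8, allelic fraction 0.7, isoform proportions
    0.913/0.83/0.738 by dosage, +2 regulon loading shift, 1.5 viral
    log-odds shift for MS).
    """

    n_donors: int = 81
    group_sizes: tuple = (33, 16, 16, 16)
    group_names: tuple = ("MS", "OIND", "NIND", "IIH")
    n_snps: int = 2000
    n_ld_blocks: int = 100
    ld_rho: float = 0.8
    maf_range: tuple = (0.1, 0.5)
    n_genes: int = 300
    cell_types: tuple = ("T_CD4", "T_CD8", "B")
    cells_per_donor_range: tuple = (50, 200)
    nb_dispersion: float = 0.5
    donor_re_sd: float = 0.3
    cell_depth_sd: float = 0.3  # lognormal cell-depth factor (sd on log scale)
    base_log_mean: float = -1.2  # mean of per-gene log base expression
    base_log_sd: float = 1.0
    n_populations: int = 2  # ancestral populations for a non-trivial kinship
    pop_divergence: float = 0.05  # Balding-Nichols F; 0 disables structure
    low_posterior_frac: float = 0.02
    planted_eqtls: list = None
    planted_ase: list = None
    planted_usage_qtl: list = None
    planted_regulons: list = None
    planted_factor_disease: list = None
    viral_effect: float = 1.5
    n_factors: int = 30
    n_tfs: int = 20
    regulon_size_range: tuple = (20, 80)
    n_viruses: int = 30
    viral_base_logit: float = -6.0
    ase_null_snps: int = 20
    ase_depth: int = 30
    ase_null_phi: float = 0.02
    usage_phi: float = 0.02
    usage_depth_mean: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.planted_eqtls is None:
            self.planted_eqtls = [PlantedEqtl(10, self.snp_near_gene(10), 0.8, self.cell_types[0])]
        if self.planted_ase is None:
            self.planted_ase = [PlantedAse(min(500, self.n_snps - 1), 0.7, 0.05)]
        if self.planted_usage_qtl is None:
            g = min(20, self.n_genes - 1)
            self.planted_usage_qtl = [PlantedUsageQtl(g, self.snp_near_gene(g), (0.913, 0.83, 0.738))]
        if self.planted_regulons is None:
            self.planted_regulons = [PlantedRegulon(0, 0, 2.0)]
        if self.planted_factor_disease is None:
            self.planted_factor_disease = [PlantedFactorDisease(1, self.cell_types[0], 1.0)]
        self.planted_eqtls = [e if isinstance(e, PlantedEqtl) else PlantedEqtl(*e) for e in self.planted_eqtls]
        self.planted_ase = [a if isinstance(a, PlantedAse) else PlantedAse(*a) for a in self.planted_ase]
        self.planted_usage_qtl = [
            u if isinstance(u, PlantedUsageQtl) else PlantedUsageQtl(*u) for u in self.planted_usage_qtl
        ]
        # snp=None means "the SNP nearest the planted gene's midpoint"
        for e in self.planted_eqtls:
            if e.snp is None:
                e.snp = self.snp_near_gene(e.gene)
        for u in self.planted_usage_qtl:
            if u.snp is None:
                u.snp = self.snp_near_gene(u.gene)
        self.planted_regulons = [
            r if isinstance(r, PlantedRegulon) else PlantedRegulon(*r) for r in self.planted_regulons
        ]
        self.planted_factor_disease = [
            f if isinstance(f, PlantedFactorDisease) else PlantedFactorDisease(*f)
            for f in self.planted_factor_disease
        ]
        self.validate()

    # -- deterministic genome layout -------------------------------------
    def snp_positions(self) -> np.ndarray:
        return 1 + SNP_SPACING * np.arange(self.n_snps)

    def gene_table(self) -> pd.DataFrame:
        span = self.n_snps * SNP_SPACING
        starts = 1 + np.round(np.arange(self.n_genes) * span / self.n_genes).astype(int)
        return pd.DataFrame(
            dict(
                gene=[f"gene{g:04d}" for g in range(self.n_genes)],
                chrom="1",
                start=starts,
                end=starts + GENE_LENGTH - 1,
            )
        )

    def snp_near_gene(self, gene: int) -> int:
        """Index of the SNP closest to the gene's midpoint."""
        span = self.n_snps * SNP_SPACING
        start = 1 + round(gene * span / self.n_genes)
        mid = start + GENE_LENGTH // 2
        return int(np.clip(round((mid - 1) / SNP_SPACING), 0, self.n_snps - 1))

    def validate(self) -> None:
        if sum(self.group_sizes) != self.n_donors:
            raise ConfigError("group_sizes must sum to n_donors")
        if len(self.group_sizes) != len(self.group_names):
            raise ConfigError("group_sizes and group_names length mismatch")
        if not 0 <= self.ld_rho < 1:
            raise ConfigError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must be a pair in (0, 0.5]")
        if len(self.cell_types) < 3:
            raise ConfigError("need at least 3 cell types")
        lo, hi = self.cells_per_donor_range
        if not (0 < lo <= hi):
            raise ConfigError("invalid cells_per_donor_range")
        for e in self.planted_eqtls:
            if not (0 <= e.gene < self.n_genes and 0 <= e.snp < self.n_snps):
                raise ConfigError(f"planted eQTL out of range: {e}")
            if e.cell_type is not None and e.cell_type not in self.cell_types:
                raise ConfigError(f"unknown cell type in planted eQTL: {e}")
        for a in self.planted_ase:
            if not 0 <= a.snp < self.n_snps:
                raise ConfigError(f"planted ASE SNP out of range: {a}")
            if not 0 < a.mean_af < 1:
                raise ConfigError("planted mean_AF must be in (0, 1)")
            if not 0 <= a.phi < 1:
                raise ConfigError("planted phi must be in [0, 1)")
        for u in self.planted_usage_qtl:
            if not (0 <= u.gene < self.n_genes and 0 <= u.snp < self.n_snps):
                raise ConfigError(f"planted usage QTL out of range: {u}")
            if not all(0 < p < 1 for p in u.psi) or len(u.psi) != 3:
                raise ConfigError("usage psi must be a triple in (0, 1)")
        for r in self.planted_regulons:
            if not (0 <= r.factor < self.n_factors and 0 <= r.tf < self.n_tfs):
                raise ConfigError(f"planted regulon out of range: {r}")
        for f in self.planted_factor_disease:
            if not 0 <= f.factor < self.n_factors or f.cell_type not in self.cell_types:
                raise ConfigError(f"planted factor-disease effect out of range: {f}")

    def donor_frame(self) -> pd.DataFrame:
        groups = np.repeat(list(self.group_names), list(self.group_sizes))
        return pd.DataFrame(
            dict(donor=[f"D{i:03d}" for i in range(self.n_donors)], group=groups)
        )


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    """Per-stage RNG so each simulate_* call is independently reproducible."""
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stage]))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(cfg: SimConfig) -> GenotypeTable:
    """LD-structured biallelic dosages via a thresholded Gaussian copula.

    Haplotype alleles within an LD block share a latent factor with
    loading sqrt(ld_rho); each allele is the indicator that the latent
    Gaussian falls below the allele-frequency quantile, and the dosage
    is the sum over the two haplotypes (hence Hardy-Weinberg by
    construction within a population).
    """
    rng = _rng(cfg, 1)
    donors = cfg.donor_frame()
    pops = np.arange(cfg.n_donors) % max(cfg.n_populations, 1)
    base_freq = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    if cfg.pop_divergence > 0 and cfg.n_populations > 1:
        F = cfg.pop_divergence
        a = base_freq * (1 - F) / F
        b = (1 - base_freq) * (1 - F) / F
        pop_freq = np.clip(rng.beta(a, b, size=(cfg.n_populations, cfg.n_snps)), 0.01, 0.99)
    else:
        pop_freq = np.tile(base_freq, (max(cfg.n_populations, 1), 1))

    block = np.minimum(
        np.arange(cfg.n_snps) * cfg.n_ld_blocks // cfg.n_snps, cfg.n_ld_blocks - 1
    )
    from scipy.stats import norm

    thresh = norm.ppf(pop_freq[pops])  # donor x snp quantile threshold
    dosage = np.zeros((cfg.n_donors, cfg.n_snps))
    sq_rho, sq_res = np.sqrt(cfg.ld_rho), np.sqrt(1 - cfg.ld_rho)
    for _hap in range(2):
        u = rng.standard_normal((cfg.n_donors, cfg.n_ld_blocks))
        z = sq_rho * u[:, block] + sq_res * rng.standard_normal((cfg.n_donors, cfg.n_snps))
        dosage += (z < thresh).astype(float)

    r2 = rng.uniform(0.5, 1.0, size=cfg.n_snps)
    planted = {e.snp for e in cfg.planted_eqtls}
    planted |= {a.snp for a in cfg.planted_ase}
    planted |= {u.snp for u in cfg.planted_usage_qtl}
    r2[list(planted)] = np.maximum(r2[list(planted)], 0.95)

    posterior = np.clip(rng.beta(40, 1, size=dosage.shape), 0, 1)
    low = rng.random(dosage.shape) < cfg.low_posterior_frac
    low[:, list(planted)] = False
    posterior[low] = rng.uniform(0.05, 0.39, size=int(low.sum()))

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=cfg.n_snps)]
    alt = bases[(np.array([list("ACGT").index(r) for r in ref]) + rng.integers(1, 4, size=cfg.n_snps)) % 4]
    snps = pd.DataFrame(
        dict(
            id=[f"snp{j:05d}" for j in range(cfg.n_snps)],
            chrom="1",
            pos=cfg.snp_positions(),
            ref=ref,
            alt=alt,
            r2=r2,
        ),
        columns=SNP_COLUMNS,
    )
    return GenotypeTable(
        donors=donors["donor"].tolist(), snps=snps, dosage=dosage, call_posterior=posterior
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSim:
    counts: np.ndarray  # cell x gene UMI counts
    cell_meta: pd.DataFrame  # cell, donor, group, cell_type
    gene_meta: pd.DataFrame  # gene, chrom, start, end
    donor_log_mean: np.ndarray  # donor x gene baseline log mean (a_g + b_dg)


def _nb_draw(rng, mean, dispersion):
    """Gamma-Poisson negative binomial with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def simulate_expression(cfg: SimConfig, geno: GenotypeTable) -> ExpressionSim:
    """Cell-by-gene NB counts with donor random effects and planted cis-eQTLs.

    Count model per cell i of donor d, gene g:
    ``count ~ NB(mean = depth_i * exp(a_g + b_dg + beta * dosage_d),
    dispersion)`` with the eQTL term applied only in the planted cell
    type; ``b_dg ~ N(0, donor_re_sd)`` and ``depth_i`` lognormal.
    """
    rng = _rng(cfg, 2)
    donors = cfg.donor_frame()
    lo, hi = cfg.cells_per_donor_range
    n_cells = rng.integers(lo, hi + 1, size=cfg.n_donors)
    donor_idx = np.repeat(np.arange(cfg.n_donors), n_cells)
    total_cells = int(n_cells.sum())
    ct = rng.integers(0, len(cfg.cell_types), size=total_cells)
    depth = np.exp(rng.normal(0.0, cfg.cell_depth_sd, size=total_cells))

    a_g = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=cfg.n_genes)
    b_dg = rng.normal(0.0, cfg.donor_re_sd, size=(cfg.n_donors, cfg.n_genes))
    donor_log_mean = a_g[None, :] + b_dg

    log_mu = donor_log_mean[donor_idx] + np.log(depth)[:, None]
    for e in cfg.planted_eqtls:
        ct_name = e.cell_type or cfg.cell_types[0]
        ct_idx = cfg.cell_types.index(ct_name)
        dos = np.nan_to_num(geno.dosage[:, e.snp], nan=np.nanmean(geno.dosage[:, e.snp]))
        mask = ct == ct_idx
        log_mu[mask, e.gene] += e.beta * dos[donor_idx[mask]]

    counts = _nb_draw(rng, np.exp(log_mu), cfg.nb_dispersion)
    cell_meta = pd.DataFrame(
        dict(
            cell=[f"cell{i:06d}" for i in range(total_cells)],
            donor=donors["donor"].to_numpy()[donor_idx],
            group=donors["group"].to_numpy()[donor_idx],
            cell_type=np.array(cfg.cell_types)[ct],
        )
    )
    return ExpressionSim(
        counts=counts.astype(np.int64),
        cell_meta=cell_meta,
        gene_meta=cfg.gene_table(),
        donor_log_mean=donor_log_mean,
    )


# ---------------------------------------------------------------------------
# allele-specific expression
# ---------------------------------------------------------------------------

def simulate_allele_counts(cfg: SimConfig, geno: GenotypeTable) -> pd.DataFrame:
    """Per-donor allele counts at heterozygous SNPs (ASE input).

    For each selected SNP, heterozygous donors get a NB total UMI count
    per cell type and a beta-binomial alt count; planted SNPs use their
    (mean_AF, phi), all others the balanced null (mean_AF = 0.5).
    Homozygous donors are excluded: ASE is defined on heterozygotes.
    """
    rng = _rng(cfg, 3)
    donors = cfg.donor_frame()
    calls = hard_calls(geno.dosage)
    genes = cfg.gene_table()
    gene_mid = (genes["start"] + genes["end"]) // 2

    planted = {a.snp: a for a in cfg.planted_ase}
    extra = [j for j in np.linspace(0, cfg.n_snps - 1, cfg.ase_null_snps, dtype=int) if j not in planted]
    snp_idx = sorted(set(planted) | set(extra))

    rows = []
    for j in snp_idx:
        het = np.flatnonzero(calls[:, j] == 1)
        if j in planted and het.size == 0:
            raise ConfigError(f"no heterozygous donors for planted ASE SNP {j}")
        mu = planted[j].mean_af if j in planted else 0.5
        phi = planted[j].phi if j in planted else cfg.ase_null_phi
        pos = geno.snps.loc[j, "pos"]
        gene = genes.loc[(gene_mid - pos).abs().idxmin(), "gene"]
        for d in het:
            for ct in cfg.cell_types:
                total = int(_nb_draw(rng, np.array(float(cfg.ase_depth)), cfg.nb_dispersion))
                alt = int(betabinom_rvs(np.array([total]), mu, phi, rng)[0]) if total > 0 else 0
                rows.append(
                    dict(
                        donor=donors.loc[d, "donor"],
                        snp=geno.snps.loc[j, "id"],
                        gene=gene,
                        cell_type=ct,
                        ref_count=total - alt,
                        alt_count=alt,
                        genotype=1,
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# isoform usage
# ---------------------------------------------------------------------------

def simulate_isoform_counts(
    cfg: SimConfig, geno: GenotypeTable, cell_meta: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-cell two-isoform counts with genotype-set long-isoform proportion.

    The long-isoform share psi is chosen by the donor's dosage at the
    planted SNP per usage-QTL triple, with beta-binomial noise on the
    per-cell total.  Cells with zero total contribute nothing.
    """
    rng = _rng(cfg, 4)
    if cell_meta is None:
        donors = cfg.donor_frame()
        lo, hi = cfg.cells_per_donor_range
        n = (lo + hi) // 2
        cell_meta = pd.DataFrame(
            dict(
                cell=[f"cell{i:06d}" for i in range(n * cfg.n_donors)],
                donor=np.repeat(donors["donor"].to_numpy(), n),
                cell_type=np.resize(list(cfg.cell_types), n * cfg.n_donors),
            )
        )
    calls = hard_calls(geno.dosage)
    donor_pos = {d: i for i, d in enumerate(cfg.donor_frame()["donor"])}
    genes = cfg.gene_table()
    rows = []
    for u in cfg.planted_usage_qtl:
        psi = np.asarray(u.psi)
        dos = calls[[donor_pos[d] for d in cell_meta["donor"]], u.snp]
        dos = np.nan_to_num(dos, nan=1.0).astype(int)
        total = rng.poisson(cfg.usage_depth_mean, size=len(cell_meta))
        keep = total > 0
        long = betabinom_rvs(total[keep], psi[dos[keep]], cfg.usage_phi, rng)
        sub = cell_meta.loc[keep].reset_index(drop=True)
        rows.append(
            pd.DataFrame(
                dict(
                    cell=sub["cell"],
                    donor=sub["donor"],
                    cell_type=sub["cell_type"],
                    gene=genes.loc[u.gene, "gene"],
                    snp=geno.snps.loc[u.snp, "id"],
                    dosage=dos[keep],
                    long_count=long,
                    short_count=total[keep] - long,
                )
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["cell", "donor", "cell_type", "gene", "snp", "dosage", "long_count", "short_count"]
    )


# ---------------------------------------------------------------------------
# factors, regulons, viral matrix
# ---------------------------------------------------------------------------

def simulate_factors_and_viral(cfg: SimConfig, cell_meta: pd.DataFrame):
    """Factor model with planted regulon loadings, regulon matrix, viral UMIs.

    Returns ``(FactorModel, regulon_df, virus_df)`` where ``regulon_df``
    is a binary gene x TF membership frame and ``virus_df`` a cell x
    virus UMI count frame indexed like ``cell_meta``.
    """
    rng = _rng(cfg, 5)
    genes = cfg.gene_table()["gene"].tolist()
    n_cells = len(cell_meta)

    W = rng.standard_normal((cfg.n_genes, cfg.n_factors))
    T = np.zeros((cfg.n_genes, cfg.n_tfs), dtype=int)
    lo, hi = cfg.regulon_size_range
    for t in range(cfg.n_tfs):
        k = int(rng.integers(lo, hi + 1))
        T[rng.choice(cfg.n_genes, size=min(k, cfg.n_genes), replace=False), t] = 1
    for r in cfg.planted_regulons:
        W[T[:, r.tf] == 1, r.factor] += r.loading_shift

    Z = rng.standard_normal((n_cells, cfg.n_factors))
    donors = cfg.donor_frame().set_index("donor")
    is_ms_cell = (cell_meta["group"] == cfg.group_names[0]).to_numpy()
    donor_ids = donors.index.tolist()
    donor_noise = rng.normal(0.0, 0.3, size=(len(donor_ids), cfg.n_factors))
    donor_lookup = {d: i for i, d in enumerate(donor_ids)}
    cell_donor = np.array([donor_lookup[d] for d in cell_meta["donor"]])
    for f in cfg.planted_factor_disease:
        shift = f.donor_shift * is_ms_cell.astype(float) + donor_noise[cell_donor, f.factor]
        mask = (cell_meta["cell_type"] == f.cell_type).to_numpy()
        Z[mask, f.factor] += shift[mask]

    factor_names = [f"factor{k}" for k in range(cfg.n_factors)]
    # the matrix the factor model "was fit to": its own reconstruction plus
    # unit noise, so every factor explains a meaningful share of variance
    Yf = Z @ W.T + rng.standard_normal((n_cells, cfg.n_genes))
    model = FactorModel(
        Z=pd.DataFrame(Z, index=cell_meta["cell"], columns=factor_names),
        W=pd.DataFrame(W, index=genes, columns=factor_names),
        cell_meta=cell_meta.set_index("cell")[["donor", "group", "cell_type"]],
        expression=pd.DataFrame(Yf, index=cell_meta["cell"], columns=genes),
    )
    regulon_df = pd.DataFrame(T, index=genes, columns=[f"TF{t:02d}" for t in range(cfg.n_tfs)])

    base = rng.normal(cfg.viral_base_logit, 0.7, size=cfg.n_viruses)
    logit = base[None, :] + cfg.viral_effect * is_ms_cell[:, None]
    presence = rng.random((n_cells, cfg.n_viruses)) < 1.0 / (1.0 + np.exp(-logit))
    counts = np.where(presence, 1 + rng.poisson(0.3, size=presence.shape), 0)
    virus_df = pd.DataFrame(
        counts, index=cell_meta["cell"], columns=[f"virus{v:02d}" for v in range(cfg.n_viruses)]
    )
    return model, regulon_df, virus_df


# ---------------------------------------------------------------------------
# ground truth + full dataset
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted effects plus the realized quantities needed to verify recovery."""

    config: SimConfig
    planted_snp_dosage: dict  # snp index -> per-donor hard-call dosages
    donor_log_mean: np.ndarray | None = None  # donor x gene baseline log mean

    def to_dict(self) -> dict:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            if isinstance(x, np.generic):
                return x.item()
            return x

        cfg = plain(asdict(self.config))
        return dict(
            config=cfg,
            planted_snp_dosage={int(k): [float(x) for x in v] for k, v in self.planted_snp_dosage.items()},
            donor_log_mean=None
            if self.donor_log_mean is None
            else np.asarray(self.donor_log_mean).round(6).tolist(),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, default_flow_style=None)


@dataclass
class SimData:
    config: SimConfig
    genotypes: GenotypeTable
    expression: ExpressionSim
    allele_counts: pd.DataFrame
    isoform_counts: pd.DataFrame
    factor_model: FactorModel
    regulons: pd.DataFrame
    viral: pd.DataFrame
    truth: GroundTruth


def simulate_all(cfg: SimConfig) -> SimData:
    """Run every generator stage and bundle outputs with the ground truth."""
    geno = simulate_genotypes(cfg)
    expr = simulate_expression(cfg, geno)
    allele = simulate_allele_counts(cfg, geno)
    iso = simulate_isoform_counts(cfg, geno, expr.cell_meta)
    model, regulons, viral = simulate_factors_and_viral(cfg, expr.cell_meta)
    planted_snps = sorted(
        {e.snp for e in cfg.planted_eqtls}
        | {a.snp for a in cfg.planted_ase}
        | {u.snp for u in cfg.planted_usage_qtl}
    )
    calls = hard_calls(geno.dosage)
    truth = GroundTruth(
        config=cfg,
        planted_snp_dosage={j: calls[:, j].tolist() for j in planted_snps},
        donor_log_mean=expr.donor_log_mean,
    )
    return SimData(cfg, geno, expr, allele, iso, model, regulons, viral, truth)


def write_dataset(data: SimData, outdir) -> None:
    """Write the bundle as plain-text artifacts (VCF, MTX, TSV, YAML)."""
    import os
    from scipy import io as spio
    from scipy import sparse

    from .genotype import write_vcf

    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    write_vcf(data.genotypes, p("genotypes.vcf"))
    spio.mmwrite(p("counts.mtx"), sparse.csr_matrix(data.expression.counts))
    data.expression.cell_meta.to_csv(p("cells.tsv"), sep="\t", index=False)
    data.expression.gene_meta.to_csv(p("genes.tsv"), sep="\t", index=False)
    data.allele_counts.to_csv(p("allele_counts.tsv"), sep="\t", index=False)
    data.isoform_counts.to_csv(p("isoform_counts.tsv"), sep="\t", index=False)
    data.factor_model.Z.to_csv(p("factor_values.tsv"), sep="\t")
    data.factor_model.W.to_csv(p("factor_weights.tsv"), sep="\t")
    if data.factor_model.expression is not None:
        data.factor_model.expression.round(4).to_csv(p("factor_expression.tsv"), sep="\t")
    data.regulons.to_csv(p("regulons.tsv"), sep="\t")
    data.viral.to_csv(p("viral_counts.tsv"), sep="\t")
    data.truth.save(p("ground_truth.yaml"))


def read_counts(mtx_path, cells_path, genes_path):
    """Round-trip reader for the MTX + TSV expression artifacts."""
    from scipy import io as spio

    counts = np.asarray(spio.mmread(mtx_path).todense()).astype(np.int64)
    cells = pd.read_csv(cells_path, sep="\t")
    genes = pd.read_csv(genes_path, sep="\t")
    return counts, cells, genes
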