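"""Factor-model downstream statistics: disease association and regulon enrichment.

Takes a (synthetic) factor model — cell x factor values Z and gene x
factor weights W — and runs the variance-explained filter, the
donor-level permutation test of disease association, and the regulon
enrichment of W^T T against random gene sets of matched size.
"""
from csf_scqtl import SimConfig, simulate_all
from csf_scqtl.factors import factor_disease_scan, regulon_enrichment

cfg = SimConfig(n_donors=40, group_sizes=(16, 8, 8, 8), n_snps=100, n_ld_blocks=10,
                n_genes=80, cells_per_donor_range=(20, 50), n_factors=10, n_tfs=6,
                ase_null_snps=2, seed=5)
data = simulate_all(cfg)

assoc = factor_disease_scan(data.factor_model, n_perm=2000, seed=0)
planted = cfg.planted_factor_disease[0]
row = assoc[(assoc["factor"] == f"factor{planted.factor}")
            & (assoc["cell_type"] == planted.cell_type)]
print(f"{len(assoc)} factor-cell-type pairs pass the 1% variance filter")
print(f"planted disease factor (factor{planted.factor} in {planted.cell_type}): "
      f"effect {row['effect'].iloc[0]:.3f}, permutation p {row['p'].iloc[0]:.4g}, "
      f"significant at 10% FDR: {bool(row['significant'].iloc[0])}")

enrich = regulon_enrichment(data.factor_model.W, data.regulons, n_samples=2000, seed=0)
reg = cfg.planted_regulons[0]
hit = enrich[(enrich["factor"] == f"factor{reg.factor}") & (enrich["tf"] == f"TF{reg.tf:02d}")]
print(f"\nplanted regulon TF{reg.tf:02d} on factor{reg.factor}: aggregated weight "
      f"{hit['score'].iloc[0]:.1f}, empirical p {hit['p'].iloc[0]:.4g} "
      f"(floor 1/{2000 + 1})")
null_p = enrich.loc[~((enrich['factor'] == f'factor{reg.factor}')
                      & (enrich['tf'] == f'TF{reg.tf:02d}')), 'p']
print(f"other factor-TF pairs with p > 0.05: {(null_p > 0.05).mean():.0%}")
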