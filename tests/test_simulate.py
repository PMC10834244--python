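import numpy as np
import pandas as pd
import pytest

from csf_scqtl.genotype import hard_calls, minor_allele_frequency
from csf_scqtl.simulate import (
    ConfigError,
    PlantedUsageQtl,
    SimConfig,
    simulate_all,
    simulate_allele_counts,
    simulate_expression,
    simulate_genotypes,
    simulate_isoform_counts,
    write_dataset,
)


class TestConfig:
    def test_group_sizes_must_sum(self):
        with pytest.raises(ConfigError, match="sum to n_donors"):
            SimConfig(n_donors=10, group_sizes=(5, 2, 2, 2))

    def test_planted_index_out_of_range(self):
        with pytest.raises(ConfigError, match="out of range"):
            SimConfig(n_donors=8, group_sizes=(2, 2, 2, 2), n_genes=5, n_snps=50,
                      planted_eqtls=[(7, 2, 0.5)], planted_ase=[], planted_usage_qtl=[])

    def test_psi_outside_unit_interval(self):
        with pytest.raises(ConfigError, match="psi"):
            SimConfig(n_donors=8, group_sizes=(2, 2, 2, 2),
                      planted_usage_qtl=[PlantedUsageQtl(0, 0, (0.9, 1.2, 0.5))])

    def test_bad_maf_range(self):
        with pytest.raises(ConfigError, match="maf_range"):
            SimConfig(n_donors=8, group_sizes=(2, 2, 2, 2), maf_range=(0.0, 0.6))


class TestGenotypes:
    def test_deterministic(self, tiny_cfg):
        a = simulate_genotypes(tiny_cfg)
        b = simulate_genotypes(tiny_cfg)
        np.testing.assert_array_equal(a.dosage, b.dosage)
        np.testing.assert_array_equal(a.call_posterior, b.call_posterior)
        assert a.snps.equals(b.snps)

    def test_dosages_hard_calls(self, tiny_data):
        d = tiny_data.genotypes.dosage
        assert set(np.unique(d)) <= {0.0, 1.0, 2.0}

    def test_no_ld_when_rho_zero(self):
        cfg = SimConfig(n_donors=500, group_sizes=(200, 100, 100, 100), n_snps=40,
                        n_ld_blocks=4, ld_rho=0.0, pop_divergence=0.0, seed=3)
        g = simulate_genotypes(cfg)
        r = np.corrcoef(g.dosage.T)
        off = np.abs(r[np.triu_indices(40, k=1)])
        assert off.max() < 0.2
        assert np.median(off) < 0.1

    def test_high_ld_within_block(self):
        # narrow MAF band so the copula discretization keeps pairwise r high
        cfg = SimConfig(n_donors=500, group_sizes=(200, 100, 100, 100), n_snps=20,
                        n_ld_blocks=2, ld_rho=0.95, maf_range=(0.3, 0.35),
                        pop_divergence=0.0, seed=3)
        g = simulate_genotypes(cfg)
        block0 = g.dosage[:, :10]
        r = np.corrcoef(block0.T)
        off = np.abs(r[np.triu_indices(10, k=1)])
        assert off.mean() > 0.7

    def test_maf_in_configured_band(self):
        cfg = SimConfig(n_donors=400, group_sizes=(100, 100, 100, 100), n_snps=60,
                        n_ld_blocks=6, maf_range=(0.2, 0.4), pop_divergence=0.0, seed=5)
        g = simulate_genotypes(cfg)
        mafs = np.array([minor_allele_frequency(g.dosage[:, j]) for j in range(60)])
        assert (mafs > 0.1).mean() > 0.95  # sampling noise around the band


class TestExpression:
    def test_deterministic(self, tiny_cfg, tiny_data):
        again = simulate_expression(tiny_cfg, tiny_data.genotypes)
        np.testing.assert_array_equal(again.counts, tiny_data.expression.counts)

    def test_planted_slope_recovered_on_log_scale(self):
        cfg = SimConfig(
            n_donors=200, group_sizes=(80, 40, 40, 40), n_snps=40, n_ld_blocks=4,
            n_genes=10, cells_per_donor_range=(40, 40), base_log_mean=1.0,
            donor_re_sd=0.2, maf_range=(0.3, 0.4), pop_divergence=0.0,
            planted_eqtls=[(3, 20, 0.5, "T_CD4")], planted_ase=[], planted_usage_qtl=[],
            seed=11,
        )
        geno = simulate_genotypes(cfg)
        expr = simulate_expression(cfg, geno)
        mask = (expr.cell_meta["cell_type"] == "T_CD4").to_numpy()
        counts = expr.counts[mask, 3].astype(float)
        donors = expr.cell_meta.loc[mask, "donor"]
        donor_mean = pd.Series(counts).groupby(donors.to_numpy()).mean()
        donor_ids = cfg.donor_frame().set_index("donor")
        dos = geno.dosage[[donor_ids.index.get_loc(d) for d in donor_mean.index], 20]
        y = np.log(donor_mean.to_numpy())
        slope = np.polyfit(dos, y, 1)[0]
        assert slope == pytest.approx(0.5, abs=0.12)

    def test_null_gene_uncorrelated_with_dosage(self, tiny_cfg, tiny_data):
        geno, expr = tiny_data.genotypes, tiny_data.expression
        gene = 30  # no planted effect
        donors = expr.cell_meta["donor"]
        dm = pd.Series(expr.counts[:, gene]).groupby(donors.to_numpy()).mean()
        donor_ids = tiny_cfg.donor_frame().set_index("donor")
        dos = geno.dosage[[donor_ids.index.get_loc(d) for d in dm.index], 5]
        r = np.corrcoef(dos, dm.to_numpy())[0, 1]
        assert abs(r) < 0.5


class TestAlleleCounts:
    def test_heterozygotes_only(self, tiny_cfg, tiny_data):
        calls = hard_calls(tiny_data.genotypes.dosage)
        donor_pos = {d: i for i, d in enumerate(tiny_data.genotypes.donors)}
        snp_pos = {s: j for j, s in enumerate(tiny_data.genotypes.snps["id"])}
        for _, row in tiny_data.allele_counts.iterrows():
            assert calls[donor_pos[row["donor"]], snp_pos[row["snp"]]] == 1

    def test_planted_fraction_recovered(self):
        cfg = SimConfig(n_donors=200, group_sizes=(80, 40, 40, 40), n_snps=30,
                        n_ld_blocks=3, n_genes=5, planted_ase=[(4, 0.7, 0.05)],
                        planted_eqtls=[], planted_usage_qtl=[], ase_null_snps=3,
                        pop_divergence=0.0, seed=2)
        geno = simulate_genotypes(cfg)
        tab = simulate_allele_counts(cfg, geno)
        planted = tab[tab["snp"] == geno.snps.loc[4, "id"]]
        frac = planted["alt_count"].sum() / (planted["alt_count"] + planted["ref_count"]).sum()
        assert frac == pytest.approx(0.7, abs=0.03)
        null = tab[tab["snp"] != geno.snps.loc[4, "id"]]
        nf = null["alt_count"].sum() / (null["alt_count"] + null["ref_count"]).sum()
        assert nf == pytest.approx(0.5, abs=0.03)


class TestIsoformCounts:
    def test_monotone_pooled_share(self, tiny_cfg, tiny_data):
        iso = tiny_data.isoform_counts
        pooled = iso.groupby("dosage").apply(
            lambda d: d["long_count"].sum() / (d["long_count"] + d["short_count"]).sum(),
            include_groups=False,
        )
        vals = pooled.sort_index().to_numpy()
        assert (np.diff(vals) < 0).all()  # 0.913 > 0.83 > 0.738 by dosage

    def test_zero_total_cells_absent(self, tiny_data):
        tot = tiny_data.isoform_counts["long_count"] + tiny_data.isoform_counts["short_count"]
        assert (tot > 0).all()


class TestBundleAndRoundTrip:
    def test_simulate_all_deterministic(self, tiny_cfg, tiny_data):
        again = simulate_all(tiny_cfg)
        np.testing.assert_array_equal(again.genotypes.dosage, tiny_data.genotypes.dosage)
        np.testing.assert_array_equal(again.expression.counts, tiny_data.expression.counts)
        pd.testing.assert_frame_equal(again.allele_counts, tiny_data.allele_counts)
        pd.testing.assert_frame_equal(again.viral, tiny_data.viral)

    def test_written_dataset_round_trips(self, tiny_data, tmp_path):
        from csf_scqtl.simulate import read_counts
        import yaml

        write_dataset(tiny_data, tmp_path)
        counts, cells, genes = read_counts(
            tmp_path / "counts.mtx", tmp_path / "cells.tsv", tmp_path / "genes.tsv"
        )
        np.testing.assert_array_equal(counts, tiny_data.expression.counts)
        assert len(cells) == len(tiny_data.expression.cell_meta)
        with open(tmp_path / "ground_truth.yaml") as fh:
            gt = yaml.safe_load(fh)
        assert gt["config"]["seed"] == tiny_data.config.seed
        assert set(map(int, gt["planted_snp_dosage"])) == set(tiny_data.truth.planted_snp_dosage)

    def test_ground_truth_records_planted_dosages(self, tiny_data):
        calls = hard_calls(tiny_data.genotypes.dosage)
        for j, dos in tiny_data.truth.planted_snp_dosage.items():
            np.testing.assert_array_equal(np.asarray(dos), calls[:, j])
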