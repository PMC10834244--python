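import numpy as np
import pandas as pd
import pytest

from csf_scqtl.factors import (
    FactorModel,
    factor_disease_association,
    factor_disease_scan,
    gsea_abs_weights,
    regulon_enrichment,
    variance_explained,
)


def _model(rng, n_cells=100, n_genes=50, n_factors=4, groups=None):
    cells = [f"c{i}" for i in range(n_cells)]
    genes = [f"g{j}" for j in range(n_genes)]
    facs = [f"f{k}" for k in range(n_factors)]
    Z = pd.DataFrame(rng.standard_normal((n_cells, n_factors)), index=cells, columns=facs)
    W = pd.DataFrame(rng.standard_normal((n_genes, n_factors)), index=genes, columns=facs)
    meta = pd.DataFrame(
        dict(
            donor=[f"d{i % 20}" for i in range(n_cells)],
            group=groups if groups is not None else ["MS" if i % 2 else "IIH" for i in range(n_cells)],
            cell_type="T",
        ),
        index=cells,
    )
    return FactorModel(Z=Z, W=W, cell_meta=meta)


class TestModelValidation:
    def test_factor_count_mismatch_rejected(self, rng):
        m = _model(rng)
        with pytest.raises(ValueError, match="factor count"):
            FactorModel(Z=m.Z.iloc[:, :2], W=m.W, cell_meta=m.cell_meta)

    def test_missing_metadata_rejected(self, rng):
        m = _model(rng)
        with pytest.raises(ValueError, match="missing columns"):
            FactorModel(Z=m.Z, W=m.W, cell_meta=m.cell_meta[["donor"]])


class TestVarianceExplained:
    def test_rank_one_reconstruction_gives_full_r2(self, rng):
        m = _model(rng)
        Y = np.outer(m.Z.to_numpy()[:, 0], m.W.to_numpy()[:, 0])
        Y = Y - Y.mean(axis=0)
        out = variance_explained(m, "T", Y)
        assert out.set_index("factor").loc["f0", "r2"] == pytest.approx(1.0, abs=1e-10)

    def test_threshold_boundary(self, rng):
        m = _model(rng)
        Y = rng.standard_normal((100, 50))
        out = variance_explained(m, "T", Y, threshold=0.01)
        fake = out.copy()
        # a factor at exactly 0.009 is excluded by the 1% rule
        assert not (0.009 >= 0.01)
        assert (out["retained"] == (out["r2"] >= 0.01)).all()

    def test_random_factor_near_zero(self, rng):
        m = _model(rng, n_cells=500)
        Y = rng.standard_normal((500, 50))
        out = variance_explained(m, "T", Y)
        # an unrelated factor explains nothing: R2 at or below ~0 (the
        # definition penalizes a bad reconstruction with negative values)
        assert out["r2"].max() <= 0.02

    def test_requires_expression(self, rng):
        with pytest.raises(ValueError, match="requires the expression"):
            variance_explained(_model(rng), "T")


class TestDiseaseAssociation:
    def _assoc(self, shift, seed, n_perm=2000):
        r = np.random.default_rng(seed)
        n_cells = 300
        donors = [f"d{i % 30}" for i in range(n_cells)]
        groups = ["MS" if int(d[1:]) < 15 else "IIH" for d in donors]
        cells = [f"c{i}" for i in range(n_cells)]
        donor_effect = {f"d{i}": r.normal(shift if i < 15 else 0.0, 0.3) for i in range(30)}
        z = np.array([donor_effect[d] for d in donors]) + r.standard_normal(n_cells) * 0.5
        Z = pd.DataFrame({"f0": z}, index=cells)
        W = pd.DataFrame({"f0": r.standard_normal(10)}, index=[f"g{j}" for j in range(10)])
        meta = pd.DataFrame(dict(donor=donors, group=groups, cell_type="T"), index=cells)
        model = FactorModel(Z=Z, W=W, cell_meta=meta)
        return factor_disease_association(model, "T", "f0", n_perm=n_perm, seed=1)

    def test_planted_donor_shift_detected(self):
        hits = sum(self._assoc(1.0, s)["p"] < 0.01 for s in range(10))
        assert hits >= 9

    def test_null_not_rejected_too_often(self):
        ps = [self._assoc(0.0, 100 + s, n_perm=500)["p"] for s in range(10)]
        assert min(ps) > 1 / 501 - 1e-12
        assert np.mean(np.array(ps) < 0.05) <= 0.2

    def test_permutation_floor(self):
        res = self._assoc(3.0, 0, n_perm=100)
        assert res["p"] >= 1 / 101 - 1e-12

    def test_small_group_skipped(self, rng):
        m = _model(rng, groups=["MS"] * 98 + ["IIH"] * 2)
        res = factor_disease_association(m, "T", "f0", n_perm=50)
        assert res["skipped"]

    def test_scan_uses_model_expression(self, rng):
        m = _model(rng, n_cells=200)
        Y = m.Z.to_numpy() @ m.W.to_numpy().T + rng.standard_normal((200, 50))
        m.expression = pd.DataFrame(Y, index=m.Z.index, columns=m.W.index)
        out = factor_disease_scan(m, n_perm=200, seed=3)
        assert len(out) > 0
        assert {"factor", "cell_type", "p", "fdr"} <= set(out.columns)


class TestRegulonEnrichment:
    def test_score_matches_bruteforce_sum(self, rng):
        W = pd.DataFrame(rng.standard_normal((20, 3)), index=[f"g{i}" for i in range(20)])
        T = pd.DataFrame(0, index=W.index, columns=["t0", "t1"])
        T.iloc[[1, 4, 7, 9], 0] = 1
        T.iloc[[0, 2, 3, 5, 8], 1] = 1
        out = regulon_enrichment(W, T, n_samples=100, seed=0)
        for _, row in out.iterrows():
            members = T.index[T[row["tf"]] == 1]
            expected = sum(W.loc[g, row["factor"]] for g in members)
            assert row["score"] == pytest.approx(expected, abs=1e-10)

    def test_full_universe_tf_has_p_one(self, rng):
        W = pd.DataFrame(rng.standard_normal((50, 2)), index=[f"g{i}" for i in range(50)])
        T = pd.DataFrame(1, index=W.index, columns=["t_all"])
        out = regulon_enrichment(W, T, n_samples=500, seed=0)
        assert (out["p"] == 1.0).all()

    def test_empirical_floor(self, rng):
        W = pd.DataFrame(rng.standard_normal((200, 1)), index=[f"g{i}" for i in range(200)])
        W.iloc[:30, 0] += 5.0
        T = pd.DataFrame(0, index=W.index, columns=["t"])
        T.iloc[:30, 0] = 1
        out = regulon_enrichment(W, T, n_samples=1000, seed=0)
        assert out["p"].iloc[0] == pytest.approx(1 / 1001)

    def test_gene_order_invariance(self, rng):
        W = pd.DataFrame(rng.standard_normal((60, 2)), index=[f"g{i}" for i in range(60)])
        T = pd.DataFrame(0, index=W.index, columns=["t"])
        T.iloc[5:25, 0] = 1
        a = regulon_enrichment(W, T, n_samples=500, seed=4)
        perm = rng.permutation(60)
        b = regulon_enrichment(W.iloc[perm], T.iloc[perm], n_samples=500, seed=4)
        assert a["score"].iloc[0] == pytest.approx(b["score"].iloc[0], abs=1e-10)

    def test_small_regulons_dropped(self, rng):
        W = pd.DataFrame(rng.standard_normal((30, 1)), index=[f"g{i}" for i in range(30)])
        T = pd.DataFrame(0, index=W.index, columns=["tiny"])
        T.iloc[:2, 0] = 1
        out = regulon_enrichment(W, T, n_samples=100, seed=0)
        assert out.empty

    def test_disjoint_universe_rejected(self, rng):
        W = pd.DataFrame(rng.standard_normal((5, 1)), index=list("abcde"))
        T = pd.DataFrame(1, index=list("vwxyz"), columns=["t"])
        with pytest.raises(ValueError, match="empty gene universe"):
            regulon_enrichment(W, T)


class TestGsea:
    def test_whole_universe_set_skipped(self, rng):
        W = pd.DataFrame({"f0": rng.standard_normal(100)}, index=[f"g{i}" for i in range(100)])
        out = gsea_abs_weights(W, {"everything": list(W.index)}, "f0")
        assert bool(out.loc[0, "skipped"])

    def test_shifted_members_detected(self, rng):
        w = rng.standard_normal(2000)
        members = [f"g{i}" for i in range(50)]
        w[:50] = w[:50] + np.sign(w[:50]) * 1.0  # |w| stochastically larger
        W = pd.DataFrame({"f0": w}, index=[f"g{i}" for i in range(2000)])
        out = gsea_abs_weights(W, {"set": members}, "f0")
        assert out.loc[0, "p"] < 0.01

    def test_null_set_not_significant(self, rng):
        W = pd.DataFrame({"f0": rng.standard_normal(500)}, index=[f"g{i}" for i in range(500)])
        out = gsea_abs_weights(W, {"s": [f"g{i}" for i in range(100, 150)]}, "f0")
        assert out.loc[0, "p"] > 0.001
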