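import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from csf_scqtl.eqtl import (
    CisWindow,
    LmmFit,
    cis_snps,
    conditional_fdr,
    fit_null_lmm,
    gene_level_permutation,
    replication_concordance,
    storey_qvalues,
)
from csf_scqtl.eqtl import test_snp as snp_association


def _snp_frame(positions, chrom="1"):
    return pd.DataFrame(
        dict(id=[f"s{i}" for i in range(len(positions))], chrom=chrom,
             pos=np.asarray(positions), ref="A", alt="G", r2=1.0)
    )


class TestCisWindow:
    def test_boundary_inclusive(self):
        win = CisWindow("g", "1", 500_000, 520_000, flank=100_000)
        snps = _snp_frame([400_000, 399_999, 620_000, 620_001, 510_000])
        got = cis_snps(win, snps)["id"].tolist()
        assert got == ["s0", "s2", "s4"]

    def test_other_chromosome_excluded(self):
        win = CisWindow("g", "1", 100, 200)
        snps = _snp_frame([150], chrom="2")
        assert cis_snps(win, snps).empty

    def test_matches_bruteforce_scan(self, rng):
        win = CisWindow("g", "1", 300_000, 340_000, flank=100_000)
        pos = rng.integers(1, 700_000, size=50)
        snps = _snp_frame(pos)
        expected = {
            f"s{i}" for i, p in enumerate(pos)
            if win.start - win.flank <= p <= win.end + win.flank
        }
        assert set(cis_snps(win, snps)["id"]) == expected

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            CisWindow("g", "1", 200, 100)


class TestNullLmm:
    def test_pure_noise_components_near_zero(self, rng):
        n = 200
        A = rng.standard_normal((n, 20))
        K = A @ A.T / 20
        reads = rng.uniform(1000, 5000, n)
        y = rng.standard_normal(n) * 2.0
        fit = fit_null_lmm(y, K, reads)
        total = np.var(y, ddof=1)
        assert fit.sigma2_g < 0.1 * total
        # sigma2_d and sigma2_e are separately weakly identified when read
        # depths are similar; their combined contribution is what matters
        assert fit.sigma2_e + fit.sigma2_d * np.mean(1 / reads) + fit.sigma2_g == pytest.approx(
            total, rel=0.10
        )

    def test_degenerate_identity_matches_sample_variance(self, rng):
        # K = I and constant reads: the three components are exchangeable and
        # the REML total must equal the sample variance exactly
        n = 60
        y = rng.standard_normal(n) * 1.7 + 3.0
        reads = np.full(n, 2000.0)
        fit = fit_null_lmm(y, np.eye(n), reads)
        total = fit.sigma2_g + fit.sigma2_e + fit.sigma2_d / 2000.0
        assert total == pytest.approx(np.var(y, ddof=1), abs=1e-6)

    def test_variance_ratio_recovered_within_twofold(self, rng):
        # block kinship, truth sigma2_g = sigma2_e = 1
        n = 200
        K = linalg.block_diag(*[np.ones((10, 10)) for _ in range(20)])
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        reads = rng.uniform(1000, 5000, n)
        ratios = []
        for _ in range(5):
            y = L @ rng.standard_normal(n) + rng.standard_normal(n)
            fit = fit_null_lmm(y, K, reads)
            eff_resid = fit.sigma2_e + fit.sigma2_d * np.mean(1 / reads)
            ratios.append(fit.sigma2_g / eff_resid)
        med = np.median(ratios)
        assert 0.5 <= med <= 2.0

    def test_too_few_donors_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 10 donors"):
            fit_null_lmm(rng.standard_normal(5), np.eye(5), np.full(5, 100.0))


class TestSnpTest:
    def test_matches_closed_form_gls_oracle(self, rng):
        # 5-donor hand-built covariance; oracle uses the explicit inverse route
        y = np.array([1.2, -0.3, 0.5, 2.0, -1.1])
        g = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        K = np.array(
            [[1.0, 0.5, 0.2, 0.0, 0.0],
             [0.5, 1.0, 0.3, 0.0, 0.0],
             [0.2, 0.3, 1.0, 0.1, 0.0],
             [0.0, 0.0, 0.1, 1.0, 0.4],
             [0.0, 0.0, 0.0, 0.4, 1.0]]
        )
        reads = np.array([100.0, 200.0, 50.0, 400.0, 150.0])
        fit = LmmFit(sigma2_g=0.7, sigma2_d=30.0, sigma2_e=0.4, loglik=0.0, converged=True)
        res = snp_association(y, g, fit, K, reads)
        Sigma = 0.7 * K + 30.0 * np.diag(1 / reads) + 0.4 * np.eye(5)
        Si = np.linalg.inv(Sigma)
        X = np.column_stack([np.ones(5), g])
        XtSiX_inv = np.linalg.inv(X.T @ Si @ X)
        beta = XtSiX_inv @ X.T @ Si @ y
        r = y - X @ beta
        s2 = (r @ Si @ r) / (5 - 2)
        se = np.sqrt(s2 * XtSiX_inv[1, 1])
        assert res["beta"] == pytest.approx(beta[1], abs=1e-8)
        assert res["se"] == pytest.approx(se, abs=1e-8)
        assert res["p"] == pytest.approx(2 * stats.norm.sf(abs(beta[1] / se)), abs=1e-8)

    def test_reduces_to_ols_when_no_random_effects(self, rng):
        n = 40
        y = rng.standard_normal(n)
        g = rng.integers(0, 3, n).astype(float)
        fit = LmmFit(0.0, 0.0, 2.5, 0.0, True)
        res = snp_association(y, g, fit, np.eye(n), np.full(n, 1000.0))
        X = np.column_stack([np.ones(n), g])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ beta
        s2 = r @ r / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res["beta"] == pytest.approx(beta[1], abs=1e-8)
        assert res["se"] == pytest.approx(se, abs=1e-8)

    def test_allele_flip_negates_beta(self, rng):
        n = 30
        y = rng.standard_normal(n)
        g = rng.integers(0, 3, n).astype(float)
        fit = LmmFit(0.2, 0.0, 1.0, 0.0, True)
        K = np.eye(n)
        reads = np.full(n, 500.0)
        a = snp_association(y, g, fit, K, reads)
        b = snp_association(y, 2 - g, fit, K, reads)
        assert b["beta"] == pytest.approx(-a["beta"], rel=1e-10)
        assert b["p"] == pytest.approx(a["p"], rel=1e-10)

    def test_missing_dosage_dropped_pairwise(self, rng):
        n = 30
        y = rng.standard_normal(n)
        g = rng.integers(0, 3, n).astype(float)
        g[:5] = np.nan
        fit = LmmFit(0.0, 0.0, 1.0, 0.0, True)
        res = snp_association(y, g, fit, np.eye(n), np.full(n, 500.0))
        assert res["n"] == 25

    def test_constant_dosage_skipped(self, rng):
        n = 20
        res = snp_association(rng.standard_normal(n), np.ones(n),
                       LmmFit(0.0, 0.0, 1.0, 0.0, True), np.eye(n), np.full(n, 100.0))
        assert res["skipped"] == "zero dosage variance"


class TestGeneLevelPermutation:
    def test_floor_when_signal_is_strong(self, rng):
        n = 80
        g = rng.integers(0, 3, n).astype(float)
        y = 2.0 * g + rng.standard_normal(n) * 0.3
        fit = LmmFit(0.0, 0.0, 1.0, 0.0, True)
        p = gene_level_permutation(y, g, fit, np.eye(n), np.full(n, 100.0),
                                   n_perm=1000, seed=1)
        assert p == pytest.approx(1 / 1001)

    def test_single_snp_matches_nominal(self, rng):
        n = 100
        g = rng.integers(0, 3, n).astype(float)
        y = 0.25 * g + rng.standard_normal(n)
        fit = LmmFit(0.0, 0.0, float(np.var(y)), 0.0, True)
        nominal = snp_association(y, g, fit, np.eye(n), np.full(n, 100.0))["p"]
        p = gene_level_permutation(y, g, fit, np.eye(n), np.full(n, 100.0),
                                   n_perm=2000, seed=5)
        # Monte-Carlo agreement of a single-SNP permutation test with the
        # parametric p (binomial error at 2000 permutations)
        mc_se = np.sqrt(nominal * (1 - nominal) / 2000)
        assert abs(p - nominal) < 4 * mc_se + 1e-3

    def test_seed_reproducible(self, rng):
        n = 50
        G = rng.integers(0, 3, size=(n, 8)).astype(float)
        y = rng.standard_normal(n)
        fit = LmmFit(0.0, 0.0, 1.0, 0.0, True)
        args = (y, G, fit, np.eye(n), np.full(n, 100.0))
        assert gene_level_permutation(*args, n_perm=300, seed=9) == gene_level_permutation(
            *args, n_perm=300, seed=9
        )


class TestStoreyQ:
    def test_all_ones(self):
        np.testing.assert_allclose(storey_qvalues(np.ones(50)), 1.0)

    def test_uniform_null_no_discoveries(self, rng):
        p = rng.uniform(size=1000)
        q = storey_qvalues(p)
        assert (q < 0.10).mean() < 0.01

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=200)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.0, 0.5]))

    def test_empty(self):
        assert storey_qvalues(np.array([])).size == 0


class TestConditionalFdr:
    def test_unmatched_genes_use_storey_branch(self):
        p = np.array([0.001, 0.5, 0.9])
        ref = np.array([np.nan, np.nan, np.nan])
        out = conditional_fdr(p, ref)
        assert (out["method"] == "storey").all()
        np.testing.assert_allclose(out["q"], storey_qvalues(p))

    def test_reference_all_null_equals_plain_storey(self):
        p = np.array([0.01, 0.2, 0.6, 0.9])
        ref = np.ones(4)
        out = conditional_fdr(p, ref)
        assert (out["method"] == "storey").all()
        np.testing.assert_allclose(out["q"], storey_qvalues(p))

    def test_conditioning_gains_power_controls_fdr(self, rng):
        # true signals concentrate in the reference-supported stratum
        m = 400
        is_true = np.zeros(m, dtype=bool)
        is_true[:60] = True
        p = rng.uniform(size=m)
        p[is_true] = rng.beta(0.08, 1.0, size=60).clip(1e-12)
        ref = np.where(np.arange(m) < 100, 1e-8, rng.uniform(size=m))
        cond = conditional_fdr(p, ref, alpha=0.10)
        plain = storey_qvalues(p) < 0.10
        n_cond = int(cond["significant"].sum())
        assert n_cond >= plain.sum()
        fdp = (~is_true[cond["significant"].to_numpy()]).mean() if n_cond else 0.0
        assert fdp <= 0.15


class TestReplication:
    def _a(self):
        return pd.DataFrame(dict(gene=["g1", "g2", "g3"], snp=["s1", "s2", "s3"],
                                 beta=[0.5, 0.4, -0.3], p=[1e-4] * 3))

    def test_rules(self):
        b = pd.DataFrame(dict(gene=["g1", "g2", "g3"], snp=["s1", "s2", "s3"],
                              beta=[0.2, 0.3, 0.8], p=[0.04, 0.06, 1e-6]))
        # g1: same sign p<0.05 -> replicated; g2: p=0.06 -> no; g3: opposite sign -> no
        assert replication_concordance(self._a(), b) == pytest.approx(1 / 3)

    def test_allele_harmonization_flips_beta(self):
        a = self._a().assign(ref=["A", "A", "A"], alt=["G", "G", "G"])
        b = pd.DataFrame(dict(gene=["g1"], snp=["s1"], beta=[-0.2], p=[0.01],
                              ref=["G"], alt=["A"]))
        # swapped alleles: external beta -0.2 flips to +0.2, concordant
        assert replication_concordance(a, b) == pytest.approx(1.0)

    def test_no_overlap_undefined(self):
        b = pd.DataFrame(dict(gene=["gX"], snp=["sX"], beta=[0.1], p=[0.01]))
        assert replication_concordance(self._a(), b) is None
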