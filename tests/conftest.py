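import numpy as np
import pytest

from csf_scqtl.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def tiny_cfg():
    """Compact study: 24 donors, 120 SNPs, 40 genes; planted defaults rescaled."""
    return SimConfig(
        n_donors=24,
        group_sizes=(9, 5, 5, 5),
        n_snps=120,
        n_ld_blocks=12,
        n_genes=40,
        cells_per_donor_range=(8, 25),
        n_factors=8,
        n_tfs=5,
        ase_null_snps=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_data(tiny_cfg):
    return simulate_all(tiny_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
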