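import numpy as np
import pytest

import mtgblup as mg


@pytest.fixture(scope="session")
def founders_small():
    """300 founders, 2 chromosomes x 400 SNPs — fast shared panel."""
    return mg.simulate_founders(300, n_chrom=2, snps_per_chrom=400, seed=11)


@pytest.fixture(scope="session")
def founders_2k():
    """2000 founders, 3 chromosomes x 1000 SNPs — the desk-scale panel."""
    return mg.simulate_founders(2000, n_chrom=3, snps_per_chrom=1000, seed=7)


@pytest.fixture(scope="session")
def grm_small(founders_small):
    return mg.compute_grm(founders_small.dosages())


@pytest.fixture(scope="session")
def toy_grm6():
    """Fixed positive-definite 6x6 relationship matrix for oracle tests."""
    rng = np.random.default_rng(123)
    w = rng.normal(size=(6, 12))
    g = w @ w.T / 12
    g[np.diag_indices(6)] += 0.05
    return g
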