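import logging

import numpy as np
import pytest

import clonalgp as cg

logging.getLogger("clonalgp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_genotypes() -> cg.GenotypeMatrix:
    """Five clones x four hand-written SNPs, one with a missing call."""
    codes = np.array([
        [0, 1, 2, 1],
        [1, 1, 0, 0],
        [2, 0, 1, 1],
        [1, 2, 0, -1],
        [0, 1, 1, 2],
    ])
    return cg.GenotypeMatrix(
        [f"c{i}" for i in range(5)], [f"s{j}" for j in range(4)], codes
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small complete simulated data set shared across tests."""
    cfg = cg.SimConfig(n_clones=120, n_snps=400, seed=42,
                       var_a=50.0, var_d=30.0, var_aa=0.0,
                       n_epistatic_pairs=0, var_e=36.0)
    g, ph, truth = cg.simulate_dataset(cfg)
    return cfg, g, ph, truth


@pytest.fixture(scope="session")
def small_kernels(small_sim):
    _, g, _, _ = small_sim
    return cg.standard_kernel_set(g, ("G_A", "G_D", "G_AA"))
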