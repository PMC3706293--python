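import numpy as np
import pytest

from diffkrr import GenotypeMatrix, SimulationConfig, simulate_genotypes


@pytest.fixture(scope="session")
def small_snp_genotypes() -> GenotypeMatrix:
    """20 outbred individuals at 5 SNP loci -- small enough for the
    tensor-product heat-kernel oracle."""
    return simulate_genotypes(SimulationConfig(n=20, p=5, n_qtl=2, seed=11))


@pytest.fixture(scope="session")
def small_binary_genotypes() -> GenotypeMatrix:
    """12 inbred lines at 8 binary loci."""
    return simulate_genotypes(SimulationConfig(n=12, p=8, n_qtl=2, inbred=True, seed=12))


@pytest.fixture(scope="session")
def hwe_genotypes() -> GenotypeMatrix:
    """Mid-sized HWE panel for relationship-matrix checks."""
    return simulate_genotypes(SimulationConfig(n=500, p=2000, n_qtl=2, seed=13))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
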