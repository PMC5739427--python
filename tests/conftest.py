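import numpy as np
import pytest

from gpplan import SimulationSpec, build_grm, simulate


@pytest.fixture(scope="session")
def panel_ne50():
    """Gene-dropped panel at drift-recombination equilibrium for Ne=50.

    Full genome architecture (30 chromosomes, 1 Morgan) with a thinned SNP
    panel (200/chromosome) to keep the fixture fast; Me does not depend on
    the SNP count once markers far outnumber segments.
    """
    spec = SimulationSpec(
        effective_size=50,
        n_generations=50,
        n_chromosomes=30,
        snps_per_chromosome=200,
        final_sample_size=500,
        seed=20,
    )
    return simulate(spec)


@pytest.fixture(scope="session")
def grm_ne50(panel_ne50):
    return build_grm(panel_ne50)


@pytest.fixture(scope="session")
def tiny_genotypes():
    """Hand-sized genotype matrix: 6 individuals x 8 SNPs on 2 chromosomes."""
    from gpplan import GenotypeMatrix

    rng = np.random.default_rng(7)
    dosage = rng.integers(0, 3, size=(6, 8)).astype(np.int8)
    return GenotypeMatrix(
        individual_ids=[f"ind{i}" for i in range(6)],
        snp_ids=[f"snp{j}" for j in range(8)],
        chromosome_of_snp=np.array([1, 1, 1, 1, 2, 2, 2, 2]),
        dosage=dosage,
    )
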