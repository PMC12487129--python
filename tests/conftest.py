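import pytest

from bloomics.simulate import SimulationConfig, generate_community
from bloomics.types import Thresholds


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def noiseless_community():
    """Small noiseless community with planted fast/slow classes, bloomers
    and enriched functional units; shared across recovery tests."""
    config = SimulationConfig(
        seed=11,
        n_genomes=20,
        n_fus=60,
        n_enriched_fus=5,
        n_bloomers=3,
        noise_sd=0.0,
        genes_per_genome=40,
        gene_length_codons=120,
        n_highly_expressed=8,
    )
    return generate_community(config)
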