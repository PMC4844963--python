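import numpy as np
import pytest

from pirnadev.simulate import (Reference, SimulationConfig, StageProfile,
                               generate_reference)


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Miniature study: 60 kb genome, 8 clusters, fast to simulate."""
    return SimulationConfig(
        genome_length=60_000,
        n_chromosomes=2,
        n_clusters=8,
        cluster_length_range=(800, 1500),
        intergenic_fraction=0.75,
        rng_seed=11,
        active_cluster_fraction=0.5,
        pool_size=120,
        n_genes=10,
        n_repeats=12,
        n_ncrnas=6,
    )


@pytest.fixture(scope="session")
def tiny_reference(tiny_config) -> Reference:
    return generate_reference(tiny_config)


@pytest.fixture(scope="session")
def study_config() -> SimulationConfig:
    """Conditions matching the study's adult-brain signal structure at 50k reads."""
    return SimulationConfig(rng_seed=101)


@pytest.fixture(scope="session")
def study_reference(study_config) -> Reference:
    return generate_reference(study_config)


def adult_brain_profile(n_reads: int = 50_000) -> StageProfile:
    """Adult brain: 7% of mapped reads in clusters, strong 1U, 26-27 nt peak."""
    return StageProfile("brain_adult", n_reads, 0.07, 0.8, [(26, 1.0)], "BT")


def juvenile_brain_profile(n_reads: int = 50_000) -> StageProfile:
    """10 dpp brain: trace cluster signal, no 1U bias."""
    return StageProfile("brain_10dpp", n_reads, 0.005, 0.25, [(26, 1.0)], "BT")


def adult_testes_profile(n_reads: int = 50_000) -> StageProfile:
    """Adult testes: nearly all reads in clusters, bimodal 26-27 + 29-30 nt."""
    return StageProfile("testes_adult", n_reads, 0.99, 0.8,
                        [(26, 0.6), (29, 0.4)], "BT")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
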