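import pytest

from mitokit.fixtures import (
    PORRECTUS_LENGTH,
    PORRECTUS_TABLE,
    SORDIDUS_LENGTH,
    SORDIDUS_TABLE,
    porrectus_features,
    sordidus_features,
)
from mitokit.synthetic_data import SimConfig, evolve_pair, simulate_ancestor


@pytest.fixture(scope="session")
def porrectus():
    return porrectus_features(), PORRECTUS_LENGTH, PORRECTUS_TABLE


@pytest.fixture(scope="session")
def sordidus():
    return sordidus_features(), SORDIDUS_LENGTH, SORDIDUS_TABLE


@pytest.fixture(scope="session")
def sim_genome():
    cfg = SimConfig(seed=11)
    genome, truth = simulate_ancestor(cfg)
    return genome, truth, cfg


@pytest.fixture(scope="session")
def sim_pair(sim_genome):
    genome, _, cfg = sim_genome
    a, b, truth = evolve_pair(genome, cfg)
    return a, b, truth
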