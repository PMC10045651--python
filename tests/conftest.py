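import pytest

from mitocomp.pipeline import build_alignments
from mitocomp.simulate import SimConfig, simulate_strains


@pytest.fixture(scope="session")
def sim():
    """One default synthetic four-strain dataset shared across tests."""
    cfg = SimConfig(seed=11)
    genomes, truths, ancestor = simulate_strains(cfg)
    return cfg, genomes, truths, ancestor


@pytest.fixture(scope="session")
def sim_genomes(sim):
    return sim[1]


@pytest.fixture(scope="session")
def sim_truths(sim):
    return sim[2]


@pytest.fixture(scope="session")
def sim_ancestor(sim):
    return sim[3]


@pytest.fixture(scope="session")
def sim_alignments(sim_genomes):
    """Per-element star alignments of the synthetic strains, genome order."""
    return build_alignments(sim_genomes)
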