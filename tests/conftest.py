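import numpy as np
import pytest

from guidetag.discovery import GuideSpec
from guidetag.simdata import make_toy_genome, standard_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome(seed=7, size=20_000, contigs=2)


@pytest.fixture(scope="session")
def guide():
    return GuideSpec(spacer="GACGCATAAAGATGAGACGC")


@pytest.fixture(scope="session")
def small_scenario():
    """A compact simulated experiment shared across pipeline tests."""
    return standard_scenario(seed=11, n_samples=6, reads_per_sample=12_000,
                             genome_size=60_000, locus_molecules=2_500,
                             control_samples=("S4", "S5", "S6"))
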