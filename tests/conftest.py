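import numpy as np
import pytest

from chromofeat.synth import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def desk_genome():
    """The default desk-scale synthetic genome (seed 42), shared across tests."""
    return simulate_genome(SimulationConfig(), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])
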