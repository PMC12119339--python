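import numpy as np
import pytest

from coopselex import Motif, ReadPool


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def uniform_pool(rng):
    """1,000 i.i.d. uniform 40-bp reads."""
    from coopselex import simulate_library
    return simulate_library(1000, length=40, seed=0)


@pytest.fixture
def sharp_motif():
    """A 4-column near-deterministic motif with consensus ACGT."""
    counts = np.full((4, 4), 1.0)
    for j, b in enumerate("ACGT"):
        counts["ACGT".index(b), j] = 97.0
    return Motif(counts, name="sharp-ACGT")


def random_pool(n, length, seed):
    from coopselex import simulate_library
    return simulate_library(n, length=length, seed=seed)


def pool_from_reads(reads, cycle=0):
    return ReadPool(list(reads), cycle=cycle)
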