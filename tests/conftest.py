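import numpy as np
import pytest

from mitoquant.genome import Genome, make_bins


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """Three autosomes + X + MT, small enough for exhaustive checks."""
    return Genome({"5": 2_000_000, "6": 2_000_000, "9": 2_000_000,
                   "X": 1_000_000, "MT": 16_569})


@pytest.fixture(scope="session")
def small_bins(small_genome):
    return make_bins(small_genome, bin_size=100_000)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240604)
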