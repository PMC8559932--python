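import numpy as np
import pytest

from lariatuss import lariat as lb
from lariatuss import simulate as sim


@pytest.fixture(scope="session")
def toy():
    """A mixed-type toy genome shared by read-only tests."""
    genome, models, truth = sim.make_toy_genome(30, seed=101)
    return genome, models, truth


@pytest.fixture(scope="session")
def toy_counts(toy):
    _, _, truth = toy
    return sim.simulate_counts(truth, seed=202)


@pytest.fixture()
def toy_intron():
    """24-nt intron with a TACTAAC box; the branch A sits at position 16
    (offset -9 from the 3' end)."""
    return lb.IntronRef("toy24", "GTATGTCGCGTACTAACTTTTCAG")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
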