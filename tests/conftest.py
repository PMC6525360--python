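import numpy as np
import pytest

from poolcross import load_reference_panel

BASES = "ACGT"


@pytest.fixture(scope="session")
def panel():
    return load_reference_panel()


@pytest.fixture(scope="session")
def eight_amplicons():
    """The high-scoring subset averaged for the headline estimates."""
    return ["1", "3", "4", "5", "8", "9", "11", "12"]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_seq(rng, length):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate_at(seq, pos, base):
    assert seq[pos] != base
    return seq[:pos] + base + seq[pos + 1 :]
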