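import pytest

from spshift import Alphabet, EnergyModel
from spshift.fixtures import random_sequence


@pytest.fixture(scope="session")
def toy():
    return EnergyModel.toy()


@pytest.fixture(scope="session")
def toy_dna():
    return EnergyModel.toy(Alphabet.DNA)


@pytest.fixture(scope="session")
def nn_rna():
    return EnergyModel.nearest_neighbor(Alphabet.RNA)


@pytest.fixture(scope="session")
def nn_dna():
    return EnergyModel.nearest_neighbor(Alphabet.DNA)


def make_random_sequences(count, lo, hi, gc=0.5, alphabet=Alphabet.RNA, base_seed=0):
    """Seeded random sequences with lengths cycling through [lo, hi]."""
    seqs = []
    for i in range(count):
        length = lo + (i % (hi - lo + 1))
        seqs.append(random_sequence(length, gc, alphabet, seed=base_seed + i))
    return seqs
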