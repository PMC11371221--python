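import numpy as np
import pytest

from orstrat import SeqRecord, simulate_species_set
from orstrat.synthetic_data import AMINO_ACIDS


@pytest.fixture
def rng():
    return np.random.default_rng(20240903)


@pytest.fixture
def ladder_tree():
    """12-species ladder: sp_k sits at node distance k from the focal tip."""
    tree, species = simulate_species_set(seed=0, n_species=12)
    return tree


def random_protein(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture
def random_records(rng):
    def make(n, min_len=30, max_len=120):
        return [
            SeqRecord(id=f"p{i}", residues=random_protein(rng, int(rng.integers(min_len, max_len))),
                      description=f"synthetic protein {i}")
            for i in range(n)
        ]
    return make
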