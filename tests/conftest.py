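import numpy as np
import pytest

from nucbarcode.core_io import SeqRecord
from nucbarcode.synthetic_data import poaceae_fixture

BASES = "ACGT"


def random_dna(rng, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def mutate(rng, seq: str, n_subs: int) -> str:
    """Apply exactly n substitutions at distinct random positions."""
    arr = list(seq)
    for i in rng.choice(len(arr), size=n_subs, replace=False):
        arr[i] = rng.permutation([b for b in BASES if b != arr[i]])[0]
    return "".join(arr)


@pytest.fixture(scope="session")
def tax():
    """Fixture taxonomy encoding the standard lineages of the study species."""
    return poaceae_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_record(rng, name: str, length: int) -> SeqRecord:
    return SeqRecord(name, random_dna(rng, length))
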