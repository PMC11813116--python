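import numpy as np
import pytest

from mirbact.formats import Alphabet, SequenceRecord


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


RNA_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def rna_complement(seq: str) -> str:
    """Perfect antiparallel complement of an RNA strand, 5'→3'."""
    return "".join(RNA_COMPLEMENT[c] for c in reversed(seq))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def mirna_22nt():
    return SequenceRecord("mir-x", "UGAGGUAGUAGGUUGUAUAGUU", Alphabet.RNA)
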