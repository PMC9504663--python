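import numpy as np
import pytest

from fishmap.sequence_io import SequenceRecord

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitution-only mutation used to plant diverged paralogs."""
    out = []
    for c in seq:
        if rng.random() < rate:
            choices = [b for b in BASES if b != c]
            out.append(choices[rng.integers(0, 3)])
        else:
            out.append(c)
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_assembly():
    """Two tiny chromosomes with a known unique segment for extraction tests."""
    return [
        SequenceRecord(id="chrA", residues="AACCGGTTACGTACGTAACC"),
        SequenceRecord(id="chrB", residues="TTTTACGTACGTNNNNacgt"),
    ]
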