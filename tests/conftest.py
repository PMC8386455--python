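import numpy as np
import pytest

from rhodoquant.align import AMINO_ACIDS, SubstitutionMatrix
from rhodoquant.annotate import load_bundled_reference
from rhodoquant.io import ProteinRecord


@pytest.fixture(scope="session")
def blosum62():
    return SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def reference():
    return load_bundled_reference()


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def random_family(rng: np.random.Generator, n: int, length: int = 50):
    """Proteins related at a range of identities: a few founders plus
    variants mutated at 5-40% of positions — gives clustering something
    non-trivial to partition."""
    founders = [random_protein(rng, length) for _ in range(max(2, n // 6))]
    records = []
    for i in range(n):
        base = founders[int(rng.integers(len(founders)))]
        seq = list(base)
        n_mut = int(rng.integers(0, int(0.4 * length) + 1))
        for j in rng.choice(length, size=n_mut, replace=False):
            seq[j] = random_protein(rng, 1)
        if rng.random() < 0.3:  # occasional truncation for length variety
            seq = seq[: int(rng.integers(int(0.7 * length), length + 1))]
        records.append(ProteinRecord(id=f"seq{i:03d}", sequence="".join(seq)))
    return records
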