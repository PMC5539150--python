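import numpy as np
import pytest

from luxcassette.io_formats import AMINO_ACIDS, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_protein(rng, ident, length=None, alphabet=AMINO_ACIDS):
    length = length or int(rng.integers(10, 60))
    seq = "".join(rng.choice(list(alphabet), size=length))
    return ProteinRecord(id=ident, sequence=seq)


@pytest.fixture
def random_proteins(rng):
    def make(n, min_len=10, max_len=60):
        return [
            random_protein(rng, f"P{i:03d}", int(rng.integers(min_len, max_len)))
            for i in range(n)
        ]

    return make
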