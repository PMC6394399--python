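import numpy as np
import pytest

from fastls import HaplotypePanel, QueryGenotype, QueryHaplotype


def random_panel(rng, max_h, max_n, alphabet=2, min_h=1, min_n=1):
    H = int(rng.integers(min_h, max_h + 1))
    n = int(rng.integers(min_n, max_n + 1))
    return HaplotypePanel(
        rng.integers(0, alphabet, (H, n)), alphabet_size=alphabet
    )


def random_query(rng, n):
    return QueryHaplotype(rng.integers(0, 2, n))


def random_genotype(rng, n):
    return QueryGenotype(rng.integers(0, 3, n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
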