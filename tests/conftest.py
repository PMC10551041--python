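import numpy as np
import pytest

from ibcrispr.genome_io import GenomeRecord
from ibcrispr.simulate import GenomeSpec, make_genome


@pytest.fixture(scope="session")
def micro_genome():
    """10-gene annotated micro-genome with one planted PAM per gene third."""
    return make_genome(GenomeSpec(n_genes=10, seed=7))


@pytest.fixture(scope="session")
def random_1kb():
    rng = np.random.default_rng(123)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=1000))
    return GenomeRecord("rand1k", seq)


def brute_hamming_hits(target: str, query: str, max_mm: int):
    """Independent exhaustive window-by-window Hamming oracle (forward only)."""
    out = []
    for i in range(len(target) - len(query) + 1):
        mm = sum(a != b for a, b in zip(target[i : i + len(query)], query))
        if mm <= max_mm:
            out.append((i, mm))
    return out
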