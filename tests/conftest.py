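import numpy as np
import pytest

from hiddenframe import fixtures
from hiddenframe.core import STOP_CODONS


def naive_stop_scan(seq: str):
    """Independent oracle: slide a width-3 window in steps of 3."""
    out = []
    for i in range(len(seq) // 3):
        codon = seq[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            out.append((codon, i + 1))
    return out


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def ibsc_like():
    return fixtures.ibsc_like()


@pytest.fixture(scope="session")
def dfrb3_like():
    return fixtures.dfrb3_like()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
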