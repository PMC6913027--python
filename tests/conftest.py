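import numpy as np
import pytest

from longsplice.io_formats import Reference
from longsplice.rdbg_index import build_index


def random_reference(seed: int, length: int = 2000, name: str = "chr1") -> Reference:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Reference({name: seq})


@pytest.fixture(scope="session")
def small_reference() -> Reference:
    return random_reference(7, length=10_000)


@pytest.fixture(scope="session")
def small_index(small_reference):
    return build_index(small_reference, k=22, l=15)
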