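import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dgrscan.types import GenomeRecord


def random_genome(seed: int, length: int, gc: float = 0.5, name: str = "g") -> GenomeRecord:
    rng = np.random.default_rng(seed)
    at = (1 - gc) / 2
    seq = "".join(rng.choice(list("ACGT"), size=length, p=[at, gc / 2, gc / 2, at]))
    return GenomeRecord(name, seq)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
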