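import numpy as np
import pytest

from rdnasim import Locus, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Desk-size configuration for smoke tests."""
    return SimConfig(n_individuals=100, generations=50, replicates=1, seed=7)


def random_locus(rng, L, frac=0.2, trunc=0.5, label_start=0):
    """Random test locus with distinct labels starting above ``label_start``."""
    codes = np.zeros(L, dtype=np.int64)
    n_ins = int(np.floor(frac * L))
    if n_ins:
        pos = rng.choice(L, size=n_ins, replace=False)
        for i, p in enumerate(pos, start=label_start + 1):
            codes[p] = -i if rng.random() < trunc else i
    return Locus(codes)
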