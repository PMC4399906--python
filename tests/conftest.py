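import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_dataset(rng):
    """A 30-subject, 5-variant dataset with a mild case burden."""
    n, k = 30, 5
    G = rng.binomial(2, [0.02, 0.05, 0.1, 0.3, 0.01], size=(n, k)).astype(np.int8)
    y = np.zeros(n, dtype=np.int8)
    y[:15] = 1
    # enrich cases at the two rarest variants so statistics are non-trivial
    G[:5, 0] = np.maximum(G[:5, 0], 1)
    G[:5, 4] = np.maximum(G[:5, 4], 1)
    return G, y
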