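import numpy as np
import pytest

from aue.phantom import PhantomConfig, sample_pair


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_pairs():
    """Eight 64x64 phantom pairs shared across tests (read-only)."""
    cfg = PhantomConfig(width=64, height=64)
    return [sample_pair(cfg, 500 + s)[0] for s in range(8)]


@pytest.fixture(scope="session")
def phantom_arrays(phantom_pairs):
    X = np.stack([p.bmode for p in phantom_pairs])
    Y = np.stack([p.elasto for p in phantom_pairs])
    return X, Y
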