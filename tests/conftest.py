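import numpy as np
import pytest

from cellalign import SyntheticConfig, generate_core_pair


@pytest.fixture(scope="session")
def clean_pair():
    """Noise-free synthetic core pair: target is exactly the transformed source."""
    cfg = SyntheticConfig(
        n_cells=600, jitter_sd=0.0, dropout_rate=0.0, split_rate=0.0,
        merge_rate=0.0, feature_jitter=0.0, seed=5,
    )
    return generate_core_pair(cfg)


@pytest.fixture(scope="session")
def degraded_pair():
    """Default degraded conditions (jitter, dropout, splits/merges), small core."""
    return generate_core_pair(SyntheticConfig(n_cells=600, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
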