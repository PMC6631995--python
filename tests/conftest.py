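import numpy as np
import pytest

from enfragility.synth import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic world shared by read-only module tests."""
    cfg = WorldConfig(seed=11, genome_length=500_000, n_enhancers=(30, 30),
                      n_pos=200, n_neg=200)
    return generate_world(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
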