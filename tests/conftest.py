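import numpy as np
import pytest

from iresunet3p.phantom import PhantomConfig, generate_case
from iresunet3p.preprocessing import BlockSpec


@pytest.fixture(scope="session")
def small_phantom_config():
    """Reduced-shape phantom preserving stage divisibility (CPU-friendly)."""
    return PhantomConfig(shape=(32, 64, 64), noise_sd=0.05, seed=7)


@pytest.fixture(scope="session")
def small_case(small_phantom_config):
    return generate_case(small_phantom_config)


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free phantom: piecewise-constant modalities."""
    return generate_case(PhantomConfig(shape=(32, 64, 64), noise_sd=0.0,
                                       seed=3))


@pytest.fixture(scope="session")
def small_block_spec():
    """Depth-16 blocks over a (32, 48, 48) crop (scaled-down method A)."""
    return BlockSpec(block_depth=16, z_step=16, crop_shape=(32, 48, 48),
                     pad_target_depth=32)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
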