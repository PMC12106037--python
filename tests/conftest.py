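import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_mm_config():
    from mm3dunet.blocks import TensorShape
    from mm3dunet.network import NetworkConfig

    return NetworkConfig(variant="mm_3dunet", base_channels=4, num_levels=2,
                         expansion_factor=2,
                         input_shape=TensorShape(1, 8, 8, 8), seed=5)


@pytest.fixture
def tiny_baseline_config():
    from mm3dunet.blocks import TensorShape
    from mm3dunet.network import NetworkConfig

    return NetworkConfig(variant="baseline_3dunet", base_channels=4, num_levels=2,
                         input_shape=TensorShape(1, 8, 8, 8), seed=5)
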