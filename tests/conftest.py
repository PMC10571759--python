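import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model_config():
    from akunet.model import ModelConfig

    return ModelConfig(input_side=32, base_filters=4,
                       convs_per_block=(1, 1, 1, 1), convlstm_grid=(2, 2),
                       seed=0)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 128x128 synthetic photograph with lesions."""
    from akunet.synthetic import SceneConfig, generate_scene

    return generate_scene(SceneConfig(size=(128, 128), seed=5,
                                      lesion_count=(2, 3)))
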