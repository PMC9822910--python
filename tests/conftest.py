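import numpy as np
import pytest

from edcrowd.density import density_from_annotations
from edcrowd.nn import MFCNN, NetworkConfig
from edcrowd.scenes import generate_scene


@pytest.fixture(scope="session")
def tiny_config() -> NetworkConfig:
    """Smallest sensible network for fast forward/backward tests."""
    return NetworkConfig(
        base_width=4, blocks_per_stage=(1, 1, 1, 1), strip_count=2, seed=11
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_config) -> MFCNN:
    return MFCNN(tiny_config)


@pytest.fixture(scope="session")
def small_scenes():
    """Eight 64x64 annotated scenes with 0-10 heads."""
    rng = np.random.default_rng(5)
    return [
        generate_scene(int(rng.integers(0, 11)), 64, 64, seed=200 + i)
        for i in range(8)
    ]


@pytest.fixture(scope="session")
def training_pairs(small_scenes):
    return [(s.image, density_from_annotations(s).values) for s in small_scenes]
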