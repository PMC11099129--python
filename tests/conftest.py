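import numpy as np
import pytest

from falconfinch.evaluation import PipelineConfig, prepare_planes
from falconfinch.synthetic_data import generate, small_spec


@pytest.fixture(scope="session")
def small_images():
    """The 110-image desk-scale synthetic set (60 benign / 50 malignant)."""
    return generate(small_spec(seed=3))


@pytest.fixture(scope="session")
def small_features(small_images):
    """Full-preprocessing features + labels for the small set."""
    cfg = PipelineConfig(seed=0)
    return prepare_planes(small_images, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
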