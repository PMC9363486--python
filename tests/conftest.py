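import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_images():
    """Small image fixture shared by fast unit tests."""
    from capsanomaly import generate_synthetic_images

    return generate_synthetic_images(n_classes=2, n_per_class=60, image_size=16, seed=7)
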