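import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_images(rng):
    """Twenty 32x32 images at 16 gray levels for oracle-equivalence checks."""
    return [rng.integers(0, 16, size=(32, 32)).astype(np.uint8) for _ in range(20)]
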