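import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_masked_image(rng, max_side=8, max_G=6):
    """A random small integer image with a random (nonempty, >=60%) mask."""
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    G = int(rng.integers(2, max_G + 1))
    image = rng.integers(0, 40, size=(h, w)).astype(float)
    mask = rng.random((h, w)) < 0.8
    if not mask.any():
        mask[h // 2, w // 2] = True
    return image, mask, G


@pytest.fixture()
def image_factory():
    return random_masked_image
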