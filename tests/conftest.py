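import numpy as np
import pytest

from usqrate import synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_pair(rng):
    """A random 16x16 reference/test image pair."""
    x = rng.random((16, 16))
    y = np.clip(x + rng.normal(0, 0.08, (16, 16)), 0.0, 1.0)
    return x, y


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 images per class at 64x64 — enough for 5-fold stratification."""
    cfg = synthgen.SynthConfig(n_per_class=12, image_size=(64, 64), seed=99)
    images, labels, manifest = synthgen.build_dataset(cfg)
    return images, np.asarray(labels), manifest
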