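import numpy as np
import pytest

from tumorcnn import (ModelSpec, PhantomConfig, avgpool2d, conv2d, dense,
                      flatten, generate)


@pytest.fixture(scope="session")
def tiny_spec() -> ModelSpec:
    """A minimal valid conv net (16x16 input) for fast training tests."""
    return ModelSpec(
        input_shape=(16, 16, 1),
        layers=(conv2d(3, 8), avgpool2d(2), conv2d(1, 4), flatten(),
                dense(16, "relu"), dense(3, "softmax")),
        name="tiny")


@pytest.fixture(scope="session")
def small_phantoms():
    """60 phantoms at 16x16 with labels, for protocol-level tests."""
    manifest = generate(PhantomConfig(n_samples=60, image_size=16, seed=7))
    return manifest.to_arrays()


@pytest.fixture(scope="session")
def phantom_manifest_64():
    """120 phantoms at 64x64 (session-cached; generation is cheap)."""
    return generate(PhantomConfig(n_samples=120, image_size=64, seed=3))
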