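import numpy as np
import pytest

from eedn.image_io import ImageFrame
from eedn.phantom import PhantomSpec, default_template, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom() -> ImageFrame:
    """A 128x128 fluoroscopy-like frame with background, devices and edges."""
    return generate_phantom(default_template(size=(128, 128)))


@pytest.fixture
def flat_spec() -> PhantomSpec:
    """Featureless spec: constant base level only."""
    return PhantomSpec(size=(64, 64), base_level=100.0, gradient_amplitude=0.0)
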