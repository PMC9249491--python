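import numpy as np
import pytest

from oskseg import PhantomSpec, generate_phantom
from oskseg.superpixel import SuperpixelMap


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomSpec(noise_sigma=0.0, bias_amplitude=0.0, seed=7))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(PhantomSpec(noise_sigma=0.05, bias_amplitude=0.1, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_sp():
    """Ten pixels in three superpixels, mixed sizes."""
    labels = np.array([0, 0, 1, 1, 1, 2, 2, 2, 2, 0])
    return SuperpixelMap(labels=labels, n_superpixels=3)
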