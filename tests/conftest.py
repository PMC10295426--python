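import numpy as np
import pytest

from veinseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """A quick noise-free phantom for module-level behaviour checks."""
    spec = PhantomSpec(height=160, width=240, n_vessels=2, width_range=(5.0, 8.0),
                       vessel_contrast=40.0, noise_sigma=0.0, seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-condition phantom (3 vessels, contrast 40, noise 8)."""
    return generate_phantom(PhantomSpec(seed=7))


def random_masks(rng, n, shape=(16, 16), p=0.5):
    return [rng.random(shape) < p for _ in range(n)]
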