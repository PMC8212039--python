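import numpy as np
import pytest

from mridenoise import ComplexImage, PhantomSpec, generate_phantom_slice


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_64():
    """A single deterministic 64x64 phantom slice (raw intensity units)."""
    spec = PhantomSpec(size=64, n_slices=1, n_subjects=2, seed=7)
    return generate_phantom_slice(spec, 0, 0)


@pytest.fixture(scope="session")
def phantom_192():
    spec = PhantomSpec(size=192, n_slices=1, n_subjects=2, seed=7)
    return generate_phantom_slice(spec, 0, 0)


@pytest.fixture
def random_complex_image(rng):
    return ComplexImage(rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32)))
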