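import numpy as np
import pytest

from fibroquant.phantom import PhantomSpec, make_slice_pair


@pytest.fixture
def small_spec() -> PhantomSpec:
    """Noiseless 64-px paired-limb phantom used across modules."""
    return PhantomSpec(
        image_size=64,
        limb_radius=13.0,
        muscle_radius=6.0,
        skin_thickness=2.0,
        reticulation_period=6.0,
        hu_noise_sd=0.0,
        seed=11,
    )


@pytest.fixture
def small_pair(small_spec):
    return make_slice_pair(small_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
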