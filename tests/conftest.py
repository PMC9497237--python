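import numpy as np
import pytest

from mprikit import PhantomSpec, generate_phantom, segment_aha16


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, motion-free default phantom (true MPRI = 2.0 everywhere)."""
    spec = PhantomSpec(noise_sigma=0.0, motion_amplitude=0, seed=11)
    rest, stress, contours, truth = generate_phantom(spec)
    return spec, rest, stress, contours, truth


@pytest.fixture(scope="session")
def clean_masks(clean_phantom):
    spec, _, _, contours, _ = clean_phantom
    return {lvl: segment_aha16(c, spec.grid_shape) for lvl, c in contours.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
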