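import numpy as np
import pytest

from hossnf import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free textured moderate-dysplasia cell with its ground truth."""
    spec = synth.default_spec("moderate_dysplasia", seed=3, noise_sigma=0.0)
    return synth.render_cell(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = synth.default_spec("moderate_dysplasia", seed=3, noise_sigma=5.0)
    return synth.render_cell(spec)


@pytest.fixture(scope="session")
def flat_phantom():
    """texture_amplitude = 0, noise = 0: each region exactly at its mean."""
    spec = synth.default_spec("moderate_dysplasia", seed=3, noise_sigma=0.0,
                              texture_scale=0.0)
    return synth.render_cell(spec)
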