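import numpy as np
import pytest

from srmtools import synthetic_data as syn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def bead_scene():
    """20 well-separated beads in a 64x64 field, PSF sigma 1.5 px."""
    return syn.generate_bead_scene(20, (64, 64), seed=7)


@pytest.fixture
def bead_frame(bead_scene):
    return syn.render_scene(bead_scene).frames[0]


@pytest.fixture
def quiet_noise():
    return syn.NoiseModel(background_offset=0.0, gaussian_sigma=0.0,
                          poisson_enabled=False, seed=0)
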