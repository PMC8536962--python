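import numpy as np
import pytest

from simounet.phantom import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_phantom_config():
    """A 16x16 cohort small enough for second-scale training smokes."""
    return PhantomConfig(
        n_subjects=4,
        slices_per_subject=(4, 6),
        image_size=(16, 16),
        brain_axis_range_px=(2.0, 2.8),
        skull_gap_px=1.0,
        noise_sd=0.03,
        master_seed=7,
    )
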