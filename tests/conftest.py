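import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def vertical_fibre_image():
    """A strongly aligned vertical fibre phantom, shared across tests."""
    from collarch.simgen import FibreFieldParams, gen_fibre_image

    params = FibreFieldParams(
        image_size=256, n_fibres=60, mean_angle_deg=0.0, kappa=1e6, seed=7
    )
    image, truth = gen_fibre_image(params)
    return image, truth
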