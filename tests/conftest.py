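import numpy as np
import pytest

from prfkit import HRFSpec, generate_bar_apertures
from prfkit.css import FitGridSpec


@pytest.fixture(scope="session")
def hrf():
    return HRFSpec()


@pytest.fixture(scope="session")
def apertures():
    """Default bar-sweep protocol at the standard grid."""
    return generate_bar_apertures()


@pytest.fixture(scope="session")
def small_apertures():
    """Coarse, cheap aperture movie for fitting tests."""
    return generate_bar_apertures(grid_px=51, steps_per_sweep=12)


@pytest.fixture(scope="session")
def fit_grid():
    return FitGridSpec.for_field(7.0, n_xy=13, n_sigma=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
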