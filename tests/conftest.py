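import numpy as np
import pytest

from chromassay.lane import GelModel, LaneProfile


@pytest.fixture
def gel():
    """Default gel model (noise on, no drift)."""
    return GelModel()


@pytest.fixture
def quiet_gel():
    """Noiseless, drift-free gel model for exact-value tests."""
    return GelModel(noise_sd=0.0, baseline_drift=0.0)


def make_profile(intensities, positions=None, **kwargs):
    intensities = np.asarray(intensities, dtype=float)
    if positions is None:
        positions = np.arange(intensities.size, dtype=float)
    kwargs.setdefault("background_subtracted", True)
    return LaneProfile(positions=positions, intensities=intensities, **kwargs)


@pytest.fixture
def profile_factory():
    return make_profile
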