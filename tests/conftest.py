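import numpy as np
import pytest

from channelphys import ph_imaging, synthgen


@pytest.fixture
def flicker_model():
    """Two-state model with the brief positive-limb kinetics (26/41 ms)."""
    return synthgen.two_state_model(mean_open_ms=26.0, mean_closed_ms=41.0,
                                    conductance_pS=60.0, erev_mV=0.0)


@pytest.fixture
def calib():
    """A mid-range sigmoid calibration spanning pH 4-9."""
    return ph_imaging.CalibCurve(ph_min=4.0, ph_max=9.0, ratio_half=1.0,
                                 slope=0.35)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
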