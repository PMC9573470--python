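import numpy as np
import pytest

import vitalradar as vr


@pytest.fixture
def default_filter():
    """The 0.02*pi clutter-rejection high-pass design."""
    return vr.design_highpass(0.02 * np.pi)


@pytest.fixture
def quiet_scene():
    """Noise-free default chest-motion scene, 60 s at 20 Hz."""
    radar = vr.RadarParams(duration=60.0, seed=0)
    motion = vr.ChestMotion()
    return radar, motion, vr.synthesize_baseband(radar, motion)
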