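import numpy as np
import pytest

from cellmag.synthio import FixtureSpec, make_oscillating_texture, make_static
from cellmag.videoio import VideoSequence


@pytest.fixture(scope="session")
def oscillating_small():
    """64×64, 4 s at 24 fps, 0.2 px drive at 1 Hz along x, noiseless."""
    spec = FixtureSpec(kind="oscillating_texture", size=(64, 64), n_frames=96,
                       frame_rate_hz=24.0, motion_freq_hz=1.0,
                       amplitude_px=0.2, direction_deg=90.0,
                       noise_sigma=0.0, seed=11)
    return make_oscillating_texture(spec)


@pytest.fixture(scope="session")
def static_small():
    """Static noisy control matched to ``oscillating_small``."""
    spec = FixtureSpec(kind="static", size=(64, 64), n_frames=96,
                       frame_rate_hz=24.0, noise_sigma=0.01, seed=12)
    return make_static(spec)


@pytest.fixture()
def rgb_video():
    rng = np.random.default_rng(0)
    frames = rng.random((6, 16, 20, 3))
    return VideoSequence(frames, frame_rate_hz=10.0,
                         channel_names=("red", "green", "blue"))
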