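import numpy as np
import pandas as pd
import pytest

from avdegrade import gaze_pipeline as gp
from avdegrade import hearing_sim as hs
from avdegrade import synthetic_data as sd

RATE = 22050.0


@pytest.fixture(scope="session")
def gen_config():
    return sd.GeneratorConfig(seed=0, audio_duration_s=1.5)


@pytest.fixture(scope="session")
def speech_audio(gen_config):
    return sd.gen_speech_like_audio(gen_config, seed=11)


@pytest.fixture(scope="session")
def nh_bank():
    return hs.design_filterbank(RATE, 1.0)


@pytest.fixture(scope="session")
def hi_bank():
    return hs.design_filterbank(RATE, 2.0)


@pytest.fixture(scope="session")
def trackpoints(gen_config):
    return sd.gen_actor_trackpoints(gen_config, n_frames=25, seed=3)


@pytest.fixture(scope="session")
def aoi_track(trackpoints):
    return gp.build_aoi_track(trackpoints)


@pytest.fixture()
def flat_trackpoints():
    """One static frame with round-number landmark positions."""
    pts = {
        "left_eyebrow_outer": (1070, 350),
        "left_eyebrow_middle": (1030, 342),
        "left_eyebrow_inner": (990, 350),
        "right_eyebrow_outer": (850, 350),
        "right_eyebrow_middle": (890, 342),
        "right_eyebrow_inner": (930, 350),
        "left_pupil": (1030, 400),
        "right_pupil": (890, 400),
        "nose_tip": (960, 480),
        "left_nostril": (990, 495),
        "right_nostril": (930, 495),
        "mouth_top": (960, 545),
        "mouth_bottom": (960, 585),
        "mouth_left": (1010, 565),
        "mouth_right": (910, 565),
        "left_hand": (1240, 900),
        "right_hand": (680, 900),
    }
    rows = [(0, name, x, y) for name, (x, y) in pts.items()]
    return pd.DataFrame(rows, columns=["frame", "landmark", "x", "y"])


def events_frame(rows):
    """Helper: build a gaze event table from (trial,kind,on,off,x,y,amp)."""
    return pd.DataFrame(
        rows, columns=["trial", "kind", "t_on", "t_off", "x", "y", "amplitude"]
    )


@pytest.fixture()
def make_events():
    return events_frame
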