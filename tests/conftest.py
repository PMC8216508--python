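import numpy as np
import pytest

from boutonquant.iglu_transients import FluorescenceMovie


@pytest.fixture
def square_mask():
    m = np.zeros((13, 13), bool)
    m[2:11, 2:11] = True
    return m


def make_movie(data, frame_interval=0.625, pixel_size=0.2,
               stimulus_times=(60.0,), mask=None):
    data = np.asarray(data, float)
    if mask is None:
        mask = np.ones(data.shape[1:], bool)
    return FluorescenceMovie(data=data, frame_interval=frame_interval,
                             pixel_size=pixel_size,
                             stimulus_times=stimulus_times, bouton_mask=mask)


@pytest.fixture
def constant_movie():
    """160 frames at 1.6 kHz (100 ms), constant 100 a.u., stimulus at 60 ms."""
    return make_movie(np.full((160, 13, 13), 100.0))
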