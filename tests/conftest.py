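import numpy as np
import pytest

from gluquant.config import SimConfig
from gluquant.movie import Movie
from gluquant.synthetic import simulate_evoked_movie


@pytest.fixture
def small_config() -> SimConfig:
    """A quick-to-simulate evoked configuration (24 boutons, 96x96)."""
    return SimConfig(image_shape=(96, 96), n_boutons=24, seed=11)


@pytest.fixture
def evoked_movie(small_config):
    return simulate_evoked_movie(small_config)


@pytest.fixture
def constant_movie():
    return Movie(np.full((20, 16, 16), 7.0), frame_interval_ms=10.0)


def make_movie(frames, interval=10.0, stim=None, **kw):
    return Movie(np.asarray(frames, dtype=float), frame_interval_ms=interval,
                 stimulus_time_ms=stim, **kw)
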