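import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from easr import EASRConfig, SemiSimSpec, TimeSeries, build_semisimulated, run_easr


@pytest.fixture(scope="session")
def semisim_default():
    """The default 60-s semi-simulated dataset (seed 0)."""
    return build_semisimulated(SemiSimSpec(seed=0))


@pytest.fixture(scope="session")
def cleaned_default(semisim_default):
    """The default dataset cleaned by the full pipeline (no pre-processing:
    the synthetic signal is already band-limited and zero-mean)."""
    return run_easr(semisim_default.contaminated, EASRConfig(preprocess=False))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sine(freq: float, fs: float = 500.0, duration: float = 10.0,
         amplitude: float = 1.0) -> TimeSeries:
    t = np.arange(int(duration * fs)) / fs
    return TimeSeries(amplitude * np.sin(2 * np.pi * freq * t), fs=fs)


@pytest.fixture
def make_sine():
    return sine
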