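import numpy as np
import pytest
from hypothesis import settings

from emgforce.synth import SynthConfig, generate_recording

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")
from emgforce.windows import WindowSpec, build_windows


@pytest.fixture(scope="session")
def default_recording():
    """The default 60 s flexion recording used by several suites."""
    return generate_recording(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def short_recording():
    """A cheap 12 s recording for structural checks."""
    return generate_recording(SynthConfig(duration=12.0, seed=7))


@pytest.fixture(scope="session")
def windowed_channel(default_recording):
    """Per-channel 200/100 windows of the default recording's first channel."""
    return build_windows(default_recording, WindowSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
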