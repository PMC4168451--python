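import numpy as np
import pytest

from eegswitch.preprocess import FilterConfig
from eegswitch.synth import SynthConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def filter_config():
    return FilterConfig()


@pytest.fixture(scope="session")
def default_run():
    """One 60 s synthetic recording under the default stated world,
    shared across tests to keep the suite fast."""
    cfg = SynthConfig()
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth
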