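import numpy as np
import pytest

from plumetrack import synth


@pytest.fixture
def timing():
    return synth.TrialTiming()


@pytest.fixture
def presets():
    return synth.default_flow_presets()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """A reduced session shared by integration-style tests: 20 trials,
    6 glomeruli with masks, default presets."""
    config = synth.SessionConfig(
        n_trials=20,
        n_medium=5,
        block_size=5,
        first_block="high",
        glomeruli=synth.default_glomerulus_population(6, frame_size=(32, 32)),
    )
    return synth.simulate_session(config, seed=21)
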