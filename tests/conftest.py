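import numpy as np
import pytest

from oswm.pipeline import PipelineConfig
from oswm.synth import SynthParams, generate_session


@pytest.fixture(scope="session")
def small_params():
    # compact session: 12 trials, short laps, few units -> fast everywhere
    return SynthParams(seed=7, n_trials=12, n_ca1=16, n_acc=6,
                       lap_duration=20.0, p_error=0.2)


@pytest.fixture(scope="session")
def small_session(small_params):
    session, gt = generate_session(small_params)
    return session, gt


@pytest.fixture(scope="session")
def default_session():
    session, gt = generate_session(SynthParams(seed=11))
    return session, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def config():
    return PipelineConfig(seed=5)
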