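import numpy as np
import pytest

from gaiteeg.config import PipelineConfig, SimConfig
from gaiteeg.synthgen import generate_dataset


@pytest.fixture(scope="session")
def tiny_sim():
    return SimConfig(n_young=1, n_old=1, n_scalp=12, n_emg=2,
                     trial_duration=15.0, n_walking_trials=1, seed=42,
                     conditions=("rest", "Flat", "High"))


@pytest.fixture(scope="session")
def tiny_dataset(tiny_sim):
    return generate_dataset(tiny_sim, "null")


@pytest.fixture()
def pipe_cfg():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
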