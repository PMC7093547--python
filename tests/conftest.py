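import numpy as np
import pytest

from oxyflow.preprocess import preprocess_recording
from oxyflow.simulate import SimulationConfig, simulate_recording


@pytest.fixture(scope="session")
def fast_cfg():
    """Simulator settings at analysis-rate natives: cheap but full-night."""
    return SimulationConfig(target_ahi=30.0, fs_spo2=3.0, fs_airflow=5.0, seed=42)


@pytest.fixture(scope="session")
def sim_recording(fast_cfg):
    return simulate_recording(fast_cfg, "fixture")


@pytest.fixture(scope="session")
def clean_recording(sim_recording):
    rec, report = preprocess_recording(sim_recording.recording)
    assert report.accepted
    return rec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
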