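import numpy as np
import pytest

from cardiovar import PipelineConfig, SimulationSpec, simulate_beat_series


@pytest.fixture(scope="session")
def quiet_spec():
    """No oscillations, no noise: a metronome heart."""
    return SimulationSpec(
        duration=60.0, mean_pi=200.0, mean_sap=120.0,
        lf_amp_pi=0.0, hf_amp_pi=0.0, lf_amp_sap=0.0, hf_amp_sap=0.0,
        noise_sd_pi=0.0, noise_sd_sap=0.0,
    )


@pytest.fixture(scope="session")
def default_series():
    """A 10-min rat-like series with the default modulation structure."""
    return simulate_beat_series(SimulationSpec(seed=11))


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
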