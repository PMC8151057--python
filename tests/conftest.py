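import numpy as np
import pytest

from choosyn import (
    EmgRecording,
    GeneratorConfig,
    generate_ground_truth,
    synthesize_emg,
)
from choosyn.extraction import NmfParams


@pytest.fixture(scope="session")
def fast_nmf() -> NmfParams:
    """Reduced restart/iteration budget for unit tests."""
    return NmfParams(max_iter=100, reruns=2, decimate=2)


@pytest.fixture(scope="session")
def truth4():
    return generate_ground_truth(4, m=12, n_cycles=30, seed=7)


@pytest.fixture(scope="session")
def recording4(truth4) -> EmgRecording:
    rec = synthesize_emg(truth4, snr_db=None, carrier_seed=1, noise_seed=2)
    return EmgRecording.from_simulated(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def generator_config() -> GeneratorConfig:
    return GeneratorConfig()
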