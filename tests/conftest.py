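import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sascakit as sk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid_1s() -> np.ndarray:
    """The default acquisition grid: 1 s sampling over 3000 s."""
    return np.arange(0.0, 3001.0)


@pytest.fixture(scope="session")
def wt148_truth() -> sk.GroundTruth:
    """One-exponential kinetics of the representative drug-sensitive cell."""
    return sk.GroundTruth("one_exp", (2.8010, 0.0008), "cell-148")


@pytest.fixture(scope="session")
def vlb58_truth() -> sk.GroundTruth:
    """Two-exponential kinetics of the representative resistant cell."""
    return sk.GroundTruth("two_exp", (0.4378, 0.0556, 0.4905, 0.0046), "cell-58")


@pytest.fixture(scope="session")
def vlb58_inhibitor_truth() -> sk.GroundTruth:
    """Incremental-phase kinetics of cell 58 after inhibitor exposure."""
    return sk.GroundTruth("two_exp", (0.1614, 0.0973, 0.3972, 0.0053), "cell-58-inhibitor")


@pytest.fixture
def noiseless_acq() -> sk.AcquisitionConfig:
    return sk.AcquisitionConfig(noise_sd=0.0, spike_rate=0.0, seed=7)
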