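import numpy as np
import pytest
from hypothesis import settings

from localglobal._utils import child_seed
from localglobal.pipeline import RunConfig, simulate_session_epochs

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reduced_cfg() -> RunConfig:
    return RunConfig.reduced(seed=1)


@pytest.fixture(scope="session")
def high_snr_epochs(reduced_cfg):
    """144-trial recording with a strong planted global effect in [300, 500) ms
    and no local effect."""
    return simulate_session_epochs(reduced_cfg, seed=child_seed(11, "fixture"),
                                   global_amplitude_uv=15.0, local_amplitude_uv=0.0)


@pytest.fixture(scope="session")
def null_epochs(reduced_cfg):
    """144-trial recording with zero effect amplitudes on both dimensions."""
    return simulate_session_epochs(reduced_cfg, seed=child_seed(12, "fixture"),
                                   global_amplitude_uv=0.0, local_amplitude_uv=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
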