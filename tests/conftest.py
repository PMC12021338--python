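import numpy as np
import pytest

from navpmc.navigator import ProbeConstants
from navpmc.synthetic import ProtocolConfig, WorldConfig


@pytest.fixture(scope="session")
def small_protocol() -> ProtocolConfig:
    """Down-scaled protocol for fast unit tests: same timing structure as the
    default, fewer channels/probes/samples."""
    return ProtocolConfig(n_channels=4, n_probes=3, fid_samples=32,
                          probe_samples=16, probe=ProbeConstants())


@pytest.fixture(scope="session")
def small_world(small_protocol) -> WorldConfig:
    return WorldConfig.random(123, small_protocol)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
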