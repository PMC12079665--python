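import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

FS = 10_000.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def cal():
    from joencode import HallCalibration

    return HallCalibration.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def ramp_hold_trace():
    """1-deg ventral ramp-and-hold at 1 deg/s, 4-s hold, 6-s rest."""
    from joencode import ProtocolSpec, make_ramp_hold

    spec = ProtocolSpec(kind="variable_position", hold_positions_deg=(-1.0,))
    return make_ramp_hold(spec)


@pytest.fixture(scope="session")
def stair_trace():
    from joencode import ProtocolSpec, make_stair

    return make_stair(ProtocolSpec.stair())
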