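import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aslrh import (
    CuffProtocol,
    ModelConstants,
    OxygenParams,
    RegulationParams,
    SubjectParams,
    calibrate,
    simulate,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants() -> ModelConstants:
    return ModelConstants()


@pytest.fixture(scope="session")
def oxygen() -> OxygenParams:
    return OxygenParams()


@pytest.fixture(scope="session")
def regulation() -> RegulationParams:
    return RegulationParams()


@pytest.fixture(scope="session")
def mean_subject() -> SubjectParams:
    return SubjectParams()


@pytest.fixture(scope="session")
def group_subject() -> SubjectParams:
    """Subject at the group-average resting perfusion Q_r/V_m."""
    return SubjectParams(f_r=4.8)


@pytest.fixture(scope="session")
def group_calib(group_subject):
    return calibrate(group_subject)


@pytest.fixture(scope="session")
def mean_calib(mean_subject):
    return calibrate(mean_subject)


@pytest.fixture(scope="session")
def sim_2min(mean_subject):
    """A standard 2-min-cuff simulation of the healthy-mean subject."""
    return simulate(mean_subject, CuffProtocol(t_cuff=120.0))


@pytest.fixture(scope="session")
def sim_5min(mean_subject):
    return simulate(mean_subject, CuffProtocol(t_cuff=300.0, t_recovery=420.0))


def assert_close(actual, expected, rtol=1e-9, atol=0.0):
    np.testing.assert_allclose(actual, expected, rtol=rtol, atol=atol)
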