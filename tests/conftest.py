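import pytest
from hypothesis import HealthCheck, settings

from ramdi.signal_model import SubjectProfile
from ramdi.simulator import HyperaemiaResponse, NoiseModel, synth_session

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def subject() -> SubjectProfile:
    return SubjectProfile("test01", age=40, sex="male", sbp=120, dbp=75, bmi=24)


@pytest.fixture(scope="session")
def quiet_session(subject):
    """One full-length session without any disturbances (construction truth)."""
    return synth_session(subject, noise=NoiseModel.quiet(), seed=101)


@pytest.fixture(scope="session")
def noisy_session(subject):
    """One full-length session at the default noise conditions."""
    return synth_session(subject, seed=102)


@pytest.fixture(scope="session")
def zero_response_session(subject):
    """Default-noise session whose occluded arm shows no hyperaemic response."""
    resp = HyperaemiaResponse(flow_surge=0.0, dilation_amplitude=0.0)
    return synth_session(subject, resp=resp, seed=103)
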