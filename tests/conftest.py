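import pytest
from hypothesis import HealthCheck, settings

from sepsim.registry import ModelParameters
from sepsim.synthetic import GroundTruth, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline() -> ModelParameters:
    return ModelParameters.baseline()


@pytest.fixture(scope="session")
def truth() -> GroundTruth:
    return GroundTruth()


@pytest.fixture(scope="session")
def noisy_cohorts(truth):
    """Default synthetic study (survivor, non-survivor, raw), fixed seed."""
    return generate_cohort(truth, seed=11)


@pytest.fixture(scope="session")
def noiseless_truth() -> GroundTruth:
    return GroundTruth(noise_sd=0.0, animal_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_cohorts(noiseless_truth):
    return generate_cohort(noiseless_truth, seed=1)
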