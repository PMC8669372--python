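import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

from pcoscreen import Instrument, RatingMap, SubjectResponse


@pytest.fixture(scope="session")
def instrument():
    return Instrument.default()


@pytest.fixture(scope="session")
def rating_map(instrument):
    return RatingMap.monotone_default(instrument)


@pytest.fixture
def most_symptomatic(instrument):
    return SubjectResponse(
        "sympt", {c.id: c.levels[-1] for c in instrument.criteria}, "A1"
    )


@pytest.fixture
def least_symptomatic(instrument):
    return SubjectResponse(
        "benign", {c.id: c.levels[0] for c in instrument.criteria}, "A4"
    )


@pytest.fixture
def tiny_cohort(instrument):
    """Three hand-built subjects: fully symptomatic, fully benign, mixed."""
    mixed = {c.id: c.levels[-1 if c.group == "physical" else 0] for c in instrument.criteria}
    return [
        SubjectResponse("s1", {c.id: c.levels[-1] for c in instrument.criteria}, "A1"),
        SubjectResponse("s2", {c.id: c.levels[0] for c in instrument.criteria}, "A4"),
        SubjectResponse("s3", mixed, "A2"),
    ]
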