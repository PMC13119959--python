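import pytest
from hypothesis import HealthCheck, settings

from biobattery import AnolyteState, ElectroParams, MicrobialParams, TerminationSpec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture()
def mp() -> MicrobialParams:
    """Baseline microbial parameter set."""
    return MicrobialParams()


@pytest.fixture()
def ep() -> ElectroParams:
    """Baseline half-cell parameter set."""
    return ElectroParams()


@pytest.fixture()
def init() -> AnolyteState:
    """Default initial anolyte: dilute inoculum, fresh medium, no mediator."""
    return AnolyteState()


@pytest.fixture()
def term() -> TerminationSpec:
    return TerminationSpec()
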