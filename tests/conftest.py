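import hypothesis
import pytest

from otcswitch import builtin_parameters, builtin_scenarios

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return builtin_parameters()


@pytest.fixture(scope="session")
def scenarios():
    return builtin_scenarios()


@pytest.fixture(scope="session")
def base(scenarios):
    return scenarios["base"]


@pytest.fixture(scope="session")
def france(params):
    return params.epidemiology["FR"], params.resources["FR"]


@pytest.fixture(scope="session")
def uk(params):
    return params.epidemiology["UK"], params.resources["UK"]
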