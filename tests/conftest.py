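import pytest
from hypothesis import HealthCheck, settings

import stratcea as sc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_case() -> sc.ParameterSet:
    return sc.make_base_case()


@pytest.fixture(scope="session")
def perfect_test() -> sc.ParameterSet:
    return sc.make_perfect_test()


@pytest.fixture(scope="session")
def base_result(base_case) -> sc.CEAResult:
    return sc.evaluate(base_case)
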