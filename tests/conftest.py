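import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import beachrisk as br

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def beaches() -> br.Scenario:
    return br.load_scenario("beaches")


@pytest.fixture(scope="session")
def literature() -> br.Scenario:
    return br.load_scenario("literature-default")


@pytest.fixture(scope="session")
def beaches_table(beaches) -> br.RiskTable:
    return br.risk_table(list(beaches.media), beaches.profile, beaches.tox)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)


def assert_printed(actual: float, printed: float) -> None:
    """Assert agreement with a published 3-significant-figure table value.

    Agreement means within one unit in the third significant digit of the
    printed value — tight enough to expose genuine model discrepancies,
    tolerant of the last-digit rounding noise published tables carry.
    """
    ulp = 10.0 ** (math.floor(math.log10(abs(printed))) - 2)
    assert abs(actual - printed) <= ulp * (1 + 1e-12), (
        f"{actual!r} does not reproduce printed value {printed!r} "
        f"(|diff| = {abs(actual - printed):.3e} > {ulp:.3e})"
    )
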