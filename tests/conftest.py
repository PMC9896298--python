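import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import popwise as pw
from popwise.nulldist import model_for_scenario

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_pop_structure():
    """The worked two-population example: 0.4 / 0.4 complements, 0.2 overlap."""
    return pw.build_structure({(1,): 0.4, (2,): 0.4, (1, 2): 0.2})


@pytest.fixture(scope="session")
def two_pop_model_unequal(two_pop_structure):
    return model_for_scenario(two_pop_structure, "two_pop_unequal")


@pytest.fixture(scope="session")
def nested_structure():
    """Three nested populations with prevalences 0.75 / 0.24 / 0.01."""
    return pw.build_structure({(1,): 0.75, (1, 2): 0.24, (1, 2, 3): 0.01})


@pytest.fixture(scope="session")
def nested_model(nested_structure):
    return model_for_scenario(nested_structure, "nested")


def lighter(model, maxpts=300_000, abseps=1e-7):
    """A reduced-quadrature copy of a model for cheap iterative tests."""
    return dataclasses.replace(model, quad_maxpts=maxpts, quad_abseps=abseps)
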