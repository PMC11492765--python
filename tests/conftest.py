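import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import goaltasks as gt
from goaltasks.tasks import make_goal_function, place_objects

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def subject():
    return gt.default_subject()


@pytest.fixture(scope="session")
def ba_env(subject):
    anthro, limits = subject
    return place_objects(limits, anthro, "BA", "near")


@pytest.fixture(scope="session")
def rs_env(subject):
    anthro, limits = subject
    return place_objects(limits, anthro, "RS", "near")


@pytest.fixture(scope="session")
def pb_env(subject):
    anthro, limits = subject
    return place_objects(limits, anthro, "PB", "near")


@pytest.fixture(scope="session")
def ba_gf(ba_env):
    return make_goal_function(ba_env)


@pytest.fixture(scope="session")
def rs_gf(rs_env):
    return make_goal_function(rs_env)


@pytest.fixture(scope="session")
def pb_gf(pb_env):
    return make_goal_function(pb_env)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240816)
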