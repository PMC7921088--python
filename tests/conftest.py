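import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import registrysim as rs

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scenario_a():
    return rs.scenario("A")


@pytest.fixture(scope="session")
def calibrated_a(scenario_a):
    return rs.calibrate_baseline(scenario_a)


@pytest.fixture(scope="session")
def other_a(scenario_a):
    return scenario_a.other_spec()


@pytest.fixture(scope="session")
def lifetable_a(scenario_a, other_a):
    return rs.make_lifetable(other_a, p_x=scenario_a.p_x)


@pytest.fixture(scope="session")
def cohort_a(scenario_a, calibrated_a, other_a):
    """One default-size scenario-A cohort shared across read-only tests."""
    return rs.simulate_cohort(scenario_a, calibrated_a, other_a, seed=12345,
                              replicate_id=0)


@pytest.fixture()
def toy_frame():
    """Three subjects: deaths at 1 and 2, censoring at 2.5."""
    return pd.DataFrame(
        {
            "age": [60.0, 70.0, 80.0],
            "time": [1.0, 2.0, 2.5],
            "dead": [True, True, False],
        }
    )


@pytest.fixture()
def flat_lifetable():
    """Constant expected rate 0.1/year over one wide band."""
    return rs.Lifetable(np.array([0.0]), np.array([120.0]), np.array([0.1]))
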