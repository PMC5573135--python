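import numpy as np
import pytest

import catrep


@pytest.fixture(scope="session")
def rb_structure():
    return catrep.make_structure("RB")


@pytest.fixture(scope="session")
def ii_structure():
    return catrep.make_structure("II")


@pytest.fixture(scope="session")
def rb_ab_schedule():
    return catrep.build_schedule("RB", "AB", seed=7)


@pytest.fixture(scope="session")
def rb_yn_schedule():
    return catrep.build_schedule("RB", "YN", seed=7)


@pytest.fixture(scope="session")
def within_rb_ab_session(rb_ab_schedule):
    """One rule-based classification session from a density-based agent."""
    return catrep.simulate_session(rb_ab_schedule, catrep.AgentConfig("within", seed=1))


@pytest.fixture(scope="session")
def between_rb_ab_session(rb_ab_schedule):
    """One rule-based classification session from a bound-based agent."""
    return catrep.simulate_session(rb_ab_schedule, catrep.AgentConfig("between", seed=1))


@pytest.fixture(scope="session")
def within_rb_yn_session(rb_yn_schedule):
    return catrep.simulate_session(rb_yn_schedule, catrep.AgentConfig("within", seed=2))


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed two-condition RB cohort for report-level tests."""
    ab = catrep.simulate_cohort("RB", "AB", 3, 3, seed=21)
    yn = catrep.simulate_cohort("RB", "YN", 3, 3, seed=22)
    sessions = ab.sessions + yn.sessions
    truth = {**ab.metadata["ground_truth"], **yn.metadata["ground_truth"]}
    return catrep.Cohort(
        sessions=sessions,
        metadata={"structure": "RB", "ground_truth": truth},
    )
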