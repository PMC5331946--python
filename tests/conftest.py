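import numpy as np
import pytest

import serolearn as sl


@pytest.fixture(scope="session")
def schedule():
    return sl.generate_schedule(seed=11)


@pytest.fixture(scope="session")
def session(schedule):
    return sl.simulate_agent(schedule, sl.GenerativeAgentParams(),
                             np.random.default_rng(101))


@pytest.fixture(scope="session")
def trace(session):
    return sl.run_bayes_learner(session)


@pytest.fixture(scope="session")
def small_cohort():
    """Five default agents on independent schedules, with Bayesian traces."""
    sessions, traces = [], []
    for i in range(5):
        sch = sl.generate_schedule(seed=400 + i)
        se = sl.simulate_agent(sch, sl.GenerativeAgentParams(),
                               np.random.default_rng(500 + i))
        sessions.append(se)
        traces.append(sl.run_bayes_learner(se))
    return sessions, traces


def make_session(schedule, choice, reward_type):
    """Hand-built session on a given schedule (no agent)."""
    n = schedule.n_trials
    return sl.BehavioralSession(
        schedule=schedule,
        choice=np.asarray(choice, dtype=int),
        reward_type=list(reward_type),
        reward_outcome=schedule.reward_mag.copy(),
        effort_outcome=schedule.effort_mag.copy(),
        clicking_rate=np.zeros(n),
        timing=[],
    )
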