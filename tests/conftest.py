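import numpy as np
import pytest

from dvbelief.synth import AgentSpec, make_schedule, probit_agent


@pytest.fixture(scope="session")
def exp1_agent_table():
    """One pooled-participant trial table from a probit agent with known
    history effects on the blocked three-granularity design."""
    schedule = make_schedule("exp1", seed=11)
    spec = AgentSpec(beta={"stimulus": 1.0, "prev_choice": 0.3,
                           "prev_choice_x_G": 0.2, "prev_stimulus": -0.4},
                     seed=11)
    return probit_agent(schedule, spec)


@pytest.fixture(scope="session")
def null_agent_table():
    """Agent with stimulus sensitivity but no history effects."""
    schedule = make_schedule("exp1", seed=23)
    return probit_agent(schedule, AgentSpec(beta={"stimulus": 1.0}, seed=23))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
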