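import numpy as np
import pytest

from habitrl import agents, task
from habitrl.models import get_spec


@pytest.fixture(scope="session")
def contingency():
    return task.build_contingency(seed=0)


@pytest.fixture(scope="session")
def learning_schedule(contingency):
    return task.build_learning_schedule(contingency, seed=0)


@pytest.fixture(scope="session")
def devaluation_schedule(contingency):
    return task.build_devaluation_schedule(contingency, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """10+10 subjects, learning phase only; shared across read-only tests."""
    return agents.simulate_cohort(n_control=10, n_cud=10, seed=42,
                                  include_devaluation=False)


@pytest.fixture(scope="session")
def full_cohort():
    """8+8 subjects with both phases (two-system devaluation behaviour)."""
    return agents.simulate_cohort(n_control=8, n_cud=8, seed=7,
                                  include_devaluation=True)


@pytest.fixture(scope="session")
def winning_spec():
    return get_spec("delta_softmax_persev")
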