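import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from remindersim import AgentParams, RunConfig, simulate_cohort

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_agent(**overrides) -> AgentParams:
    params = dict(
        p_internal=0.65,
        p_external=0.95,
        conf_internal=58.0,
        conf_external=84.0,
        subjective_ip=5.0,
        framing_shift=1.0,
        choice_slope=1.5,
        lapse=0.05,
    )
    params.update(overrides)
    return AgentParams(**params)


@pytest.fixture(scope="session")
def exp1_cohort():
    config = RunConfig(experiment=1, seed=101, n_participants=60)
    participants, trials = simulate_cohort(config)
    return config, participants, trials


@pytest.fixture(scope="session")
def exp2_cohort():
    config = RunConfig(experiment=2, seed=202, n_participants=80)
    participants, trials = simulate_cohort(config)
    return config, participants, trials


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
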