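import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tempoprep as tp
from tempoprep.pipeline import RunConfig, attach_hazard
from tempoprep.prep_models import PreparationModel

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def u_short():
    return tp.make_uncertain(1600, 120)


@pytest.fixture(scope="session")
def u_long():
    return tp.make_uncertain(2400, 120)


@pytest.fixture(scope="session")
def b_short():
    return tp.make_baseline(1600, 5)


@pytest.fixture(scope="session")
def uniform4():
    """Discrete uniform over 4 bins: the textbook hazard staircase 1/4, 1/3, 1/2, 1."""
    support = np.array([1300.0, 1350.0, 1400.0, 1450.0])
    return tp.FPDistribution(support, np.full(4, 0.25), 1375.0, 0.0, "U", (1250.0, 2750.0), 50.0)


@pytest.fixture(scope="session")
def sim_trials():
    """A small but full simulated experiment with hazard regressors attached."""
    cfg = RunConfig(seed=11, n_subjects=12, n_trials_per_block=60)
    from tempoprep.pipeline import stage_simulate

    return stage_simulate(cfg)


@pytest.fixture(scope="session")
def clean_trials(sim_trials):
    from tempoprep.preprocessing import preprocess_trials

    return preprocess_trials(sim_trials)
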