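import numpy as np
import pytest

from cardexplore import agents as ag
from cardexplore.task import TaskConfig, SMALL_SCHEDULE


@pytest.fixture(scope="session")
def uncertainty_dataset() -> ag.SimDataset:
    """30 uncertainty-guided participants, 6 experimental rounds each.

    Moderate slope on z-scored Delta-uncertainty plus a right-side and repeat
    bias; no lapse, so fitted slopes can be compared to the generative values
    without attenuation.
    """
    rng = np.random.default_rng(101)
    spec = ag.DatasetSpec(
        task=TaskConfig(session_schedule=SMALL_SCHEDULE),
        n_participants=30,
        population=ag.AgentParams(strategy="uncertainty", beta_dv=1.0,
                                  beta_side=0.1, beta_rep=0.3),
        name="uncertainty-cohort",
    )
    return ag.simulate_dataset(spec, rng)


@pytest.fixture(scope="session")
def threshold_dataset() -> ag.SimDataset:
    """100 participants with a planted overall-uncertainty threshold (tau = 1 nat)."""
    rng = np.random.default_rng(202)
    spec = ag.DatasetSpec(
        task=TaskConfig(session_schedule=SMALL_SCHEDULE),
        n_participants=100,
        population=ag.AgentParams(strategy="uncertainty", beta_dv=1.0,
                                  beta_side=0.1, beta_rep=0.3,
                                  tau=1.0, beta_int=-20.0),
        name="threshold-cohort",
    )
    return ag.simulate_dataset(spec, rng)
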