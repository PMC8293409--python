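import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from vergesize.psychometric import PFParams, slope_from_threshold
from vergesize.quest import QuestGrids, QuestPlus
from vergesize.synth import simulate_session


@pytest.fixture(scope="session")
def design_observer() -> PFParams:
    """The design-analysis observer: bias 0, threshold 5%, lapse 2%."""
    return PFParams(0.0, slope_from_threshold(5.0), 0.02, 0.02)


@pytest.fixture(scope="session")
def reduced_engine() -> QuestPlus:
    """Shared engine on the reduced lattice (tables are expensive to build)."""
    return QuestPlus(QuestGrids.reduced())


@pytest.fixture(scope="session")
def tiny_engine() -> QuestPlus:
    """Small engine whose behaviour can be checked by exhaustive enumeration."""
    grids = QuestGrids(
        alpha=np.array([-4.0, -1.0, 0.0, 2.0]),
        beta_log10=np.array([-0.9, -0.5, -0.1]),
        gamma=np.array([0.0, 0.04]),
        lambda_=np.array([0.0, 0.04]),
    )
    return QuestPlus(grids, stimulus_domain=[-12.0, -6.0, -2.0, 2.0, 6.0, 12.0])


@pytest.fixture(scope="session")
def quest_session(design_observer, reduced_engine):
    """One 200-trial adaptive session from the design observer."""
    return simulate_session(
        design_observer, rng=np.random.default_rng(7), quest=reduced_engine
    )
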