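import warnings

import numpy as np
import pytest

from dragonmorph import simulate

# boundary-variance REML fits are expected on null simulations
warnings.filterwarnings(
    "ignore", message=".*MLE may be on the boundary.*")


@pytest.fixture
def rng():
    return np.random.default_rng(20151020)


@pytest.fixture
def feature_table():
    """Four-morph colour feature table at the study's 10/7/7/11 counts."""
    return simulate.gen_feature_table(seed=11)


@pytest.fixture
def hormone_panel():
    """18-female hormone panel with the 18/11/15 timepoint availability."""
    return simulate.gen_hormone_panel(seed=12)


@pytest.fixture
def timecourse():
    """Weekly red-proportion trajectories for all four morphs."""
    return simulate.gen_timecourse(seed=13)
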