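import numpy as np
import pytest

from bupnlx.params import BupParams, NlxParams
from bupnlx.trial import Arm, NosDistribution, TrialDesign, generate_trial


@pytest.fixture(scope="session")
def bup_params():
    return BupParams()


@pytest.fixture(scope="session")
def nlx_params():
    return NlxParams()


@pytest.fixture(scope="session")
def study_trial():
    """One full-design virtual trial (46 subjects, IIV + noise + censoring)."""
    return generate_trial(seed=1)


@pytest.fixture(scope="session")
def noisefree_trial():
    """Full design, typical subjects only: no IIV, no residual, no censoring."""
    return generate_trial(seed=2, iiv=False, residual=False, censor=False)


def one_arm_design(n=12, dose=8, nos_fixed=True, times=None):
    """A reduced single-arm design for cheap estimation/diagnostic tests."""
    nos = NosDistribution(2, 2, 2.0) if nos_fixed else NosDistribution(0, 3, 2.0)
    design = TrialDesign(arms=[Arm(f"{dose}mg-single", dose, n, nos=nos)])
    if times is not None:
        times = tuple(times)
        design.sampling_times = lambda arm, _t=times: np.array((0.0,) + _t)
    return design
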