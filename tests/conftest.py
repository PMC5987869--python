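import numpy as np
import pytest

from ldpatterns import cohort


@pytest.fixture
def timing():
    return cohort.TimingParams()


@pytest.fixture
def run_design(timing):
    return cohort.generate_run_design(timing, run_index=0, seed=11)


@pytest.fixture
def small_structure():
    return cohort.GroupStructure(n_td=4, n_dl=3, n_dc=3, n_dldc=3, sigma_subject=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
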