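import numpy as np
import pytest

from walkmem import StudyConfig, simulate_cohort
from walkmem.io import save_cohort


@pytest.fixture(scope="session")
def config():
    return StudyConfig()


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated cohort (fast; reference group at
    full size so prototypes are meaningful)."""
    return simulate_cohort(seed=11, n_patients=8, n_controls=8, n_reference=12)


@pytest.fixture(scope="session")
def default_sim():
    """A cohort at the study's group sizes (27 + 27 + 12)."""
    return simulate_cohort(seed=5)


@pytest.fixture()
def cohort_dir(tmp_path, small_sim):
    """The small cohort written out as its CSV artifacts."""
    save_cohort(small_sim.cohort, tmp_path)
    return tmp_path


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
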