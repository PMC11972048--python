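import numpy as np
import pytest

from jeps.phantom import generate_cohort, micro_config
from jeps.training import prepare_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient micro-grid cohort shared by fast tests."""
    cfg = micro_config(n_patients=60, seed=42)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_prepared(small_cohort):
    cfg, patients = small_cohort
    return cfg, prepare_cohort(patients, cfg.spacing_mm, cfg.grid_shape)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
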