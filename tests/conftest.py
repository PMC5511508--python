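import numpy as np
import pytest

from neocardio.cohort import default_calibration, generate_cohort


@pytest.fixture(scope="session")
def default_cfg():
    return default_calibration()


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down study: same calibration, fewer subjects, for fast tests."""
    cfg = default_calibration()
    cfg.n_preterm = 40
    cfg.n_term = 45
    cfg.n_fetal = 30
    cfg.n_fetal_overlap = {"preterm": 4, "term": 10}
    return cfg


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
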