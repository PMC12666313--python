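import numpy as np
import pytest

from odrs import ScreenConfig
from odrs.synthetic_data import FOCAL_REGIMEN, generate_plate_set, random_truth


@pytest.fixture(scope="session")
def small_cfg() -> ScreenConfig:
    """Two-drug panel (including the focal regimen) to keep screens light."""
    return ScreenConfig(drugs=("5-FU", FOCAL_REGIMEN))


@pytest.fixture(scope="session")
def full_cfg() -> ScreenConfig:
    return ScreenConfig()


@pytest.fixture(scope="session")
def clean_screen(small_cfg):
    """One noise-free PDO plate set with its ground truth."""
    rng = np.random.default_rng(11)
    truth = random_truth("PDO-T1", small_cfg, rng)
    wells = generate_plate_set(truth, small_cfg, noise_cv=0.0, seed=1)
    return truth, wells


@pytest.fixture(scope="session")
def noisy_screen(small_cfg):
    rng = np.random.default_rng(12)
    truth = random_truth("PDO-T2", small_cfg, rng)
    wells = generate_plate_set(truth, small_cfg, noise_cv=0.08, seed=2)
    return truth, wells
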