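import numpy as np
import pytest
from hypothesis import settings

import apiat
from apiat.features import bank_tables, features_frame
from apiat.irt import ModelParams, calibrate_bank
from apiat.itemgen import GenerationConfig, generate_bank

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    return GenerationConfig(
        levels=(1, 2, 3),
        heard_counts=(3, 4),
        keys=("C", "D"),
        variations=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bank(small_config):
    return generate_bank(small_config)


@pytest.fixture(scope="session")
def small_tables(small_bank):
    return bank_tables(small_bank)


@pytest.fixture(scope="session")
def calibration_bank():
    """The full calibration grid: 300 cells x 10 variations."""
    return generate_bank(apiat.default_calibration_config(seed=0))


@pytest.fixture(scope="session")
def full_bank():
    """Calibration grid plus the level-6 extension (3600 items)."""
    return apiat.combined_bank(calibration_seed=0, extension_seed=1)


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def full_calibrated(full_bank, default_params):
    return calibrate_bank(full_bank, default_params)


@pytest.fixture(scope="session")
def calibration_features(calibration_bank):
    return features_frame(calibration_bank)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
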