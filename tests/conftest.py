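import numpy as np
import pytest

from iolscore import CohortConfig, calibrate_category_distribution

# the printed composite-score category split the generator is calibrated to
CATEGORY_TARGETS = (0.29, 0.48, 0.23)


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig()


@pytest.fixture(scope="session")
def calibrated_config(default_config):
    """Config calibrated to the low/intermediate/high category targets.

    Session-scoped: the deterministic search is run once and shared.
    """
    result = calibrate_category_distribution(
        default_config, CATEGORY_TARGETS, seed=20240101)
    return result.config


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
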