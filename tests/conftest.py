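import numpy as np
import pytest

import pcpscore as pcp


@pytest.fixture(scope="session")
def calibrated_cfg():
    """Generator config calibrated to the reference cohort medians."""
    return pcp.calibrated_config(seed=11)


@pytest.fixture(scope="session")
def default_cohort(calibrated_cfg):
    """One draw of the reference-sized cohort (828 subjects)."""
    return pcp.generate_cohort(calibrated_cfg)


@pytest.fixture(scope="session")
def power_direction_data():
    """Marker triplets whose true log-odds lies along (1, -1, 0.5)."""
    return pcp.sample_power_direction(2000, seed=421)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
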