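import numpy as np
import pandas as pd
import pytest

from nestpred.site import DUBAI, doy_to_timestamp
from nestpred.synthetic_data import ScenarioConfig, generate_temperature_field


def mk(doy: float, year: int = 2019) -> pd.Timestamp:
    """Timestamp for a fractional day of year (test shorthand)."""
    return doy_to_timestamp(year, doy)


@pytest.fixture(scope="session")
def site():
    return DUBAI


@pytest.fixture(scope="session")
def temp_field():
    """Default-calibration ambient samples and truth, shared across tests."""
    cfg = ScenarioConfig(seed=424)
    return generate_temperature_field(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
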