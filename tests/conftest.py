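import numpy as np
import pandas as pd
import pytest

from recmort.config import ScenarioConfig
from recmort.synthetic import generate_scenario


@pytest.fixture(scope="session")
def tiny_cfg() -> ScenarioConfig:
    """Two small regions over the full 2000-2010 span."""
    return ScenarioConfig(n_regions=2, pop_size=3e5, seed=7)


@pytest.fixture(scope="session")
def tiny_panels(tiny_cfg):
    return generate_scenario(tiny_cfg)


@pytest.fixture()
def year_dates():
    def make(y1: int, y2: int) -> pd.DatetimeIndex:
        return pd.date_range(f"{y1}-01-01", f"{y2}-12-31", freq="D")

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
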