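import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from chitalseason import GrowthModelParams, SimulationTruth

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params() -> GrowthModelParams:
    return GrowthModelParams()


@pytest.fixture(scope="session")
def truth_small() -> SimulationTruth:
    """A reduced simulation for fast unit tests."""
    return SimulationTruth(
        seed=7,
        n_antler_obs_per_month=60,
        n_females_culled=15,
        cull_months=("2014-10", "2015-03", "2016-10", "2018-03"),
    )


@pytest.fixture(scope="session")
def flat_rainfall() -> pd.Series:
    idx = pd.period_range("2013-01", "2018-12", freq="M")
    return pd.Series(50.0, index=idx, name="rain_mm")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
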