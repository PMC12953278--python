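import numpy as np
import pandas as pd
import pytest

from tempmort.dlnm import fit_series
from tempmort.synthetic import TrueSurface, make_region_series


@pytest.fixture(scope="session")
def surface():
    return TrueSurface()


@pytest.fixture(scope="session")
def short_series(surface):
    """Four-year synthetic series, fast enough for unit tests."""
    return make_region_series("unit", surface, start="2000-01-01", end="2003-12-31", seed=11)


@pytest.fixture(scope="session")
def fitted_short(short_series):
    """One fixed-knots fit shared by curve/attribution tests."""
    return fit_series(short_series)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_series_frame(dates, deaths, tmean):
    return pd.DataFrame({"date": dates, "deaths": deaths, "tmean": tmean})
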