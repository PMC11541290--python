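import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from riverwq.io_config import AreaMap, GuidelineSet, MonitoringTable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: Plausible regulatory-style guideline values for the 12-parameter set
#: (criteria are jurisdiction-specific; these are test fixtures, not
#: recommendations).
SI_12 = {
    "nitrate": 10.0, "nitrite": 1.0, "ammonia": 2.0,
    "fecal_coliform": 200.0, "chlorophyll_a": 30.0, "orthophosphate": 0.3,
    "doc": 6.0, "temperature": 32.0, "do": 5.0, "ph": 8.5,
    "salinity": 35.0, "tss": 30.0,
}


@pytest.fixture(scope="session")
def guidelines12() -> GuidelineSet:
    return GuidelineSet(si=dict(SI_12))


@pytest.fixture(scope="session")
def areas() -> AreaMap:
    return AreaMap({"ULPR": ("ML8", "ML9"), "DLPR": ("ML10", "ML11", "ML12")})


def make_table(rows) -> MonitoringTable:
    df = pd.DataFrame(rows, columns=["station", "date", "parameter", "value"])
    df["date"] = pd.to_datetime(df["date"])
    df["unit"] = ""
    return MonitoringTable(df)


@pytest.fixture()
def toy_table() -> MonitoringTable:
    return make_table([
        ("ML8", "2015-06-01", "tss", 12.0),
        ("ML8", "2015-06-01", "ph", 7.4),
        ("ML10", "2015-06-01", "tss", 20.0),
        ("ML10", "2015-06-01", "ph", 7.1),
    ])


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
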