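import pandas as pd
import pytest
from hypothesis import settings

from pahrisk import load_default_registry, load_fixture

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")


@pytest.fixture(scope="session")
def defaults():
    """(registry, toxicity constants, extreme-scenario exposure) defaults."""
    return load_default_registry()


@pytest.fixture(scope="session")
def pm25() -> pd.DataFrame:
    return load_fixture("pm25")


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2() -> pd.DataFrame:
    return load_fixture("table2")


@pytest.fixture(scope="session")
def pm25_maps(pm25):
    """(tc_map, fbioa_map) keyed by abbreviation, fractions of 1."""
    tc = dict(zip(pm25["analyte"], pm25["c_ng_m3"].astype(float)))
    fb = {
        row.analyte: (None if pd.isna(row.fbioa) else float(row.fbioa))
        for row in pm25.itertuples()
    }
    return tc, fb
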