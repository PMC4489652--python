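import numpy as np
import pandas as pd
import pytest

import selfexcite as sx


def make_catalog_df(rows):
    """Build a canonical event frame from (date, state, lat, lon, killed,
    firearm, suicide) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "date", "state", "latitude", "longitude", "n_killed",
            "firearm", "shooter_suicide",
        ],
    )
    df["n_shot"] = df["n_killed"]
    return df


def write_csv(tmp_path, df, name="events.csv"):
    path = tmp_path / name
    df.to_csv(path, index=False)
    return str(path)


@pytest.fixture
def small_catalog(tmp_path):
    df = make_catalog_df(
        [
            ("2010-01-01", "TX", 31.5, -99.3, 4, True, False),
            ("2010-01-01", "CA", 37.2, -119.3, 5, True, True),
            ("2010-01-02", "NY", 42.9, -75.5, 4, False, False),
            ("2010-01-05", "FL", 28.6, -82.4, 6, True, True),
            ("2010-01-09", "OH", 40.3, -82.8, 4, True, False),
        ]
    )
    return sx.read_catalog(write_csv(tmp_path, df))


@pytest.fixture(scope="session")
def contagious_series():
    """A moderately long simulated series with genuine self-excitation."""
    spec = sx.GeneratorSpec(
        n_days=3000, baseline_rate=0.08, n_secondary=0.3, t_excite=13.0
    )
    return sx.simulate_series(spec, seed=42)


@pytest.fixture(scope="session")
def null_series():
    spec = sx.GeneratorSpec(n_days=3000, baseline_rate=0.08, n_secondary=0.0)
    return sx.simulate_series(spec, seed=7)


@pytest.fixture(scope="session")
def synthetic_catalog():
    spec = sx.GeneratorSpec(seed=3)
    catalog, series = sx.simulate_catalog(spec)
    return catalog
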