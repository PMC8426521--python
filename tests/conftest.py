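import numpy as np
import pandas as pd
import pytest

from dendrovigor.climate import DailyClimateSeries
from dendrovigor.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Full-span (1920-2019) synthetic dataset with the default stand design."""
    return generate_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def small_dataset():
    """Shorter, smaller dataset for fast unit tests."""
    cfg = SyntheticConfig(start_year=1950, end_year=2019, divergence_year=2000,
                          n_trees_per_class=6, seed=77)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_climate(default_dataset):
    return default_dataset.climate


def make_climate(tm, prec=None, start="2000-01-01", latitude=41.3,
                 elevation=900.0, diurnal=10.0, **extra):
    """Build a DailyClimateSeries from raw arrays (test helper)."""
    tm = np.asarray(tm, dtype=float)
    n = len(tm)
    prec = np.zeros(n) if prec is None else np.asarray(prec, dtype=float)
    idx = pd.date_range(start, periods=n, freq="D")
    df = pd.DataFrame({"tx": tm + diurnal / 2, "tn": tm - diurnal / 2,
                       "tm": tm, "prec": prec}, index=idx)
    for k, v in extra.items():
        df[k] = v
    return DailyClimateSeries(df, latitude=latitude, elevation=elevation)
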