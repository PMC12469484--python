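import warnings

import numpy as np
import pandas as pd
import pytest

# statsmodels GLMGam emits convergence/deprecation chatter on small fits
warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)

from sahelheat.synthetic import generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (~1,800 usable days, signal at lags 3-5)."""
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def feature_table(default_dataset):
    return default_dataset["table"]


@pytest.fixture(scope="session")
def model_features(feature_table):
    return [
        c for c in feature_table.columns
        if c not in ("date", "admissions", "day_index")
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_climate_frame(dates, tmax, rhmin=None):
    """Small helper for hand-built climate tables."""
    n = len(dates)
    return pd.DataFrame(
        {
            "date": pd.to_datetime(dates),
            "tmax_c": tmax,
            "rhmin_pct": rhmin if rhmin is not None else [30.0] * n,
        }
    )
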