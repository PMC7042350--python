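import numpy as np
import pandas as pd
import pytest

from gyretrend.expressions import FEATURE_COLUMNS


@pytest.fixture
def feature_frame():
    """Small complete-case feature table with positive, in-range values."""
    rng = np.random.default_rng(7)
    n = 60
    df = pd.DataFrame({
        "jday": np.arange(n, dtype=float) * 30.0,
        "yday": (np.arange(n) % 12) * 30.0 + 15.0,
        "mld": rng.uniform(15.0, 115.0, n),
        "dgrad": rng.uniform(0.996, 0.9995, n),
        "temp": rng.uniform(19.0, 23.0, n),
        "no3": rng.uniform(30.0, 90.0, n),
        "po4": rng.uniform(2.0, 6.0, n),
        "sio2": rng.uniform(80.0, 160.0, n),
        "fuco": rng.uniform(5.0, 30.0, n),
        "chlb": rng.uniform(3.0, 12.0, n),
        "lutzea": rng.uniform(3.0, 10.0, n),
        "chla": rng.uniform(10.0, 35.0, n),
    })
    df = df[list(FEATURE_COLUMNS)]
    df["npp"] = (400.0 - 30.0 * (df["temp"] - 21.0) + 4.0 * df["fuco"]
                 + rng.normal(0, 5, n))
    return df
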