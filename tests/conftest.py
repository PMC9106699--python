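import numpy as np
import pandas as pd
import pytest

from windmatch import MatchingConstraints, SyntheticConfig, generate_dataset, match_pairs


@pytest.fixture(scope="session")
def medium_study():
    """One 2000-day synthetic study with its default-constraint matching."""
    sds = generate_dataset(SyntheticConfig(n_days=2000), seed=42)
    pairs = match_pairs(sds.observed, MatchingConstraints())
    return sds, pairs


@pytest.fixture()
def day_pair():
    """A treated/control row pair satisfying every default constraint."""
    def make(**overrides):
        base = {
            "date": pd.Timestamp("2015-06-01"), "w": 1,
            "temperature": 20.0, "wind_speed": 3.0, "humidity": 60.0,
            "pm10_lag1": 25.0, "w_lag1": 0.0, "rainfall_cat": 1,
            "weekend": 0, "holiday": 0, "bank_day": 0,
        }
        treated = dict(base)
        control = dict(base, w=0, date=pd.Timestamp("2015-07-01"))
        for key, val in overrides.items():
            side, _, name = key.partition("_") if key.startswith(("t_", "c_")) else ("", "", "")
            if side == "t":
                treated[name] = val
            elif side == "c":
                control[name] = val
            else:
                raise KeyError(key)
        return pd.Series(treated), pd.Series(control)
    return make
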