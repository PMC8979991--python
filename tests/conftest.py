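import numpy as np
import pandas as pd
import pytest

from sipipe.timeseries import AreaSpec, EnvSeries


def make_env(area_id, variable, start="2003-01", values=None, units=None):
    """Build an EnvSeries from a start month and a value sequence."""
    from sipipe.timeseries import VARIABLE_UNITS

    values = np.asarray(values, dtype=float)
    index = pd.period_range(start, periods=len(values), freq="M")
    return EnvSeries(
        area_id, variable, units or VARIABLE_UNITS[variable], pd.Series(values, index=index)
    )


@pytest.fixture
def sos_area():
    return AreaSpec("SoS", "Strait of Sicily", survey_month=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture
def clean_table():
    """Noiseless regression table with y = 0.21 + 0.21*si - 0.07*sst."""
    rng = np.random.default_rng(7)
    n = 24
    si = rng.uniform(0, 1, n)
    sst = rng.uniform(0, 1, n)
    si[0], si[1] = 0.0, 1.0
    sst[2], sst[3] = 0.0, 1.0
    return pd.DataFrame(
        {
            "area_id": ["A"] * (n // 2) + ["B"] * (n - n // 2),
            "recruit_year": list(range(2000, 2000 + n // 2)) * 2,
            "y": 0.21 + 0.21 * si - 0.07 * sst,
            "si_scaled": si,
            "sst_scaled": sst,
        }
    )
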