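import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from thermofate.calibration import TsetRange
from thermofate.io_ingest import TemperatureTrace

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def female_tset() -> TsetRange:
    """Preferred range with female-like bounds (lower 27.0, upper 33.8 degC)."""
    return TsetRange(sex="female", lower=27.0, upper=33.8, n_individuals=10)


@pytest.fixture
def hourly_trace():
    """Factory for simple hourly temperature traces."""

    def make(values, start="2018-10-01 05:00", freq="h", sensor_id="s1",
             entity="lizard", microhabitat=None):
        values = np.asarray(values, dtype=float)
        ts = pd.date_range(start, periods=len(values), freq=freq)
        return TemperatureTrace(
            sensor_id=sensor_id, entity=entity, microhabitat=microhabitat,
            timestamps=ts, values=values,
        )

    return make


@pytest.fixture
def minute_frame():
    """Factory for minute tables with given accel means."""

    def make(accel, start="2018-10-01 08:00", lizard_id="L1", tb=None):
        accel = np.asarray(accel, dtype=float)
        out = pd.DataFrame(
            {
                "lizard_id": lizard_id,
                "minute": pd.date_range(start, periods=len(accel), freq="min"),
                "accel_mean": accel,
            }
        )
        if tb is not None:
            out["tb_mean"] = np.asarray(tb, dtype=float)
        return out

    return make
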