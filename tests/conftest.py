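import numpy as np
import pandas as pd
import pytest

from heatstrain.station_io import HOURLY_COLUMNS


@pytest.fixture
def hourly_frame():
    """Two full synthetic days of plausible June observations, one station."""
    timestamps = pd.date_range("2019-06-01", periods=48, freq="h", tz="UTC")
    hours = timestamps.hour.to_numpy()
    ta = 20.0 + 6.0 * np.sin(np.pi * (hours - 8) / 12.0)
    return pd.DataFrame(
        {
            "station_id": "WAW",
            "timestamp": timestamps,
            "ta": ta,
            "vp": 15.0,
            "v10": 3.0,
            "cloud": 0.4,
        }
    )[HOURLY_COLUMNS]


@pytest.fixture
def hourly_csv(tmp_path, hourly_frame):
    path = tmp_path / "hourly.csv"
    hourly_frame.assign(
        timestamp=hourly_frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    ).to_csv(path, index=False)
    return path
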