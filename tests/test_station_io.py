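"""Reading, validation and daily aggregation of hourly station tables."""

import numpy as np
import pandas as pd
import pytest

from heatstrain.station_io import (
    CsvDialect, HourlyObservation, StationFileError,
    aggregate_daily, read_hourly, read_mortality, write_hourly,
)


def _write(tmp_path, text, name="obs.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadHourly:
    def test_well_formed_file_reads_identically(self, tmp_path):
        path = _write(
            tmp_path,
            "station_id,timestamp,ta,vp,v10,cloud\n"
            "WAW,2019-06-01T00:00:00+00:00,18.5,14.2,3.1,0.25\n"
            "WAW,2019-06-01T01:00:00+00:00,18.1,14.0,2.9,0.5\n",
        )
        frame = read_hourly(path)
        assert len(frame) == 2
        assert list(frame["ta"]) == [18.5, 18.1]
        assert frame.attrs["rejected_rows"] == []

    def test_oktas_dialect_converts_to_fraction(self, tmp_path):
        path = _write(
            tmp_path,
            "station_id,timestamp,ta,vp,v10,cloud\n"
            "WAW,2019-06-01T00:00:00+00:00,18.5,14.2,3.1,4\n",
        )
        frame = read_hourly(path, CsvDialect(cloud_unit="oktas"))
        assert frame["cloud"].iloc[0] == pytest.approx(0.5)

    def test_invalid_cloud_row_rejected_others_kept(self, tmp_path):
        path = _write(
            tmp_path,
            "station_id,timestamp,ta,vp,v10,cloud\n"
            "WAW,2019-06-01T00:00:00+00:00,18.5,14.2,3.1,9\n"
            "WAW,2019-06-01T01:00:00+00:00,18.1,14.0,2.9,6\n",
        )
        frame = read_hourly(path, CsvDialect(cloud_unit="oktas"))
        assert len(frame) == 1
        (issue,) = frame.attrs["rejected_rows"]
        assert issue["line"] == 2 and "cloud" in issue["reason"]

    def test_unparseable_timestamp_reports_line_number(self, tmp_path):
        path = _write(
            tmp_path,
            "station_id,timestamp,ta,vp,v10,cloud\n"
            "WAW,not-a-time,18.5,14.2,3.1,0.5\n"
            "WAW,2019-06-01T01:00:00+00:00,18.1,14.0,2.9,0.5\n",
        )
        frame = read_hourly(path)
        assert len(frame) == 1
        (issue,) = frame.attrs["rejected_rows"]
        assert issue["line"] == 2 and "timestamp" in issue["reason"]

    def test_missing_column_is_a_configuration_error(self, tmp_path):
        path = _write(tmp_path, "station_id,timestamp,ta,vp,v10\nWAW,2019-06-01,18,14,3\n")
        with pytest.raises(StationFileError, match="cloud"):
            read_hourly(path)

    def test_duplicate_station_hour_is_an_error(self, tmp_path):
        path = _write(
            tmp_path,
            "station_id,timestamp,ta,vp,v10,cloud\n"
            "WAW,2019-06-01T00:00:00+00:00,18.5,14.2,3.1,0.5\n"
            "WAW,2019-06-01T00:00:00+00:00,19.5,14.2,3.1,0.5\n",
        )
        with pytest.raises(StationFileError, match="duplicate"):
            read_hourly(path)

    def test_round_trip_is_identity(self, tmp_path, hourly_frame):
        path = tmp_path / "roundtrip.csv"
        write_hourly(hourly_frame, path)
        back = read_hourly(path)
        pd.testing.assert_frame_equal(back, hourly_frame, check_like=True)

    def test_observation_invariants_enforced_on_scalar_record(self):
        with pytest.raises(ValueError):
            HourlyObservation("WAW", pd.Timestamp("2019-06-01", tz="UTC"),
                              ta=20.0, vp=-1.0, v10=3.0, cloud=0.5)


class TestAggregateDaily:
    def test_constant_series_returns_constant_statistics(self, hourly_frame):
        frame = hourly_frame.assign(ta=20.0)
        daily = aggregate_daily(frame, utci=np.full(len(frame), 20.0))
        assert (daily["tmax"] == 20.0).all()
        assert (daily["tmin"] == 20.0).all()
        assert (daily["tavg"] == 20.0).all()
        assert (daily["utci_avg"] == 20.0).all()
        assert (daily["complete"]).all()

    def test_split_day_statistics(self):
        timestamps = pd.date_range("2019-06-01", periods=24, freq="h", tz="UTC")
        ta = np.where(timestamps.hour < 12, 18.0, 30.0)
        frame = pd.DataFrame(
            {"station_id": "X", "timestamp": timestamps, "ta": ta,
             "vp": 12.0, "v10": 2.0, "cloud": 0.3}
        )
        daily = aggregate_daily(frame, utci=ta.astype(float))
        row = daily.iloc[0]
        assert row["tmax"] == 30.0 and row["tmin"] == 18.0
        assert row["tavg"] == pytest.approx(24.0)
        # the midday (12 UTC) record alone feeds the *_12 statistics
        assert row["utci_avg_12"] == 30.0 and row["utci_max_12"] == 30.0

    def test_sparse_day_flagged_incomplete(self):
        timestamps = pd.date_range("2019-06-01", periods=3, freq="h", tz="UTC")
        frame = pd.DataFrame(
            {"station_id": "X", "timestamp": timestamps, "ta": 20.0,
             "vp": 12.0, "v10": 2.0, "cloud": 0.3}
        )
        daily = aggregate_daily(frame, min_valid_hours=18)
        assert not daily["complete"].iloc[0]
        assert daily["n_hours"].iloc[0] == 3

    def test_missing_midday_leaves_12utc_fields_missing(self):
        timestamps = pd.date_range("2019-06-01", periods=24, freq="h", tz="UTC")
        frame = pd.DataFrame(
            {"station_id": "X", "timestamp": timestamps, "ta": 20.0,
             "vp": 12.0, "v10": 2.0, "cloud": 0.3}
        )
        frame = frame[frame["timestamp"].dt.hour != 12]
        daily = aggregate_daily(frame, utci=np.full(len(frame), 21.0))
        assert np.isnan(daily["utci_avg_12"].iloc[0])
        assert daily["utci_avg"].iloc[0] == 21.0

    def test_aggregation_is_permutation_invariant(self, hourly_frame):
        rng = np.random.default_rng(7)
        perm = rng.permutation(len(hourly_frame))
        shuffled = hourly_frame.iloc[perm].reset_index(drop=True)
        a = aggregate_daily(hourly_frame, utci=hourly_frame["ta"].to_numpy())
        b = aggregate_daily(shuffled, utci=shuffled["ta"].to_numpy())
        pd.testing.assert_frame_equal(a, b)

    def test_misaligned_utci_rejected(self, hourly_frame):
        with pytest.raises(ValueError, match="align"):
            aggregate_daily(hourly_frame, utci=np.zeros(3))


def test_read_mortality_validates_columns_and_signs(tmp_path):
    path = tmp_path / "mort.csv"
    path.write_text("city_id,year,month,deaths,population\nWAW,2019,6,1000,1700000\n")
    frame = read_mortality(path)
    assert frame["deaths"].iloc[0] == 1000
    bad = tmp_path / "bad.csv"
    bad.write_text("city_id,year,month,deaths,population\nWAW,2019,6,-5,1700000\n")
    with pytest.raises(StationFileError):
        read_mortality(bad)
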