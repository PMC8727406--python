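"""Threshold-day counts, heat-wave detection and anomaly statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heatstrain.climatology import (
    HeatWave, anomaly, count_threshold_days, detect_heat_waves, monthly_mean,
)


def make_daily(tmax, tmin=None):
    n = len(tmax)
    return pd.DataFrame(
        {
            "station_id": "X",
            "date": pd.date_range("2019-06-01", periods=n).date,
            "tmax": tmax,
            "tmin": tmin if tmin is not None else np.asarray(tmax) - 8.0,
            "tavg": np.asarray(tmax) - 4.0,
            "complete": True,
        }
    )


def brute_force_waves(values, threshold=30.0, min_length=3):
    """Independent enumeration of all maximal above-threshold runs."""
    waves, start = [], None
    for i, v in enumerate(list(values) + [-1e9]):
        if v > threshold and start is None:
            start = i
        elif v <= threshold and start is not None:
            if i - start >= min_length:
                waves.append((start, i - start))
            start = None
    return waves


class TestCountThresholdDays:
    def test_worked_example_counts(self):
        daily = make_daily([24.9, 25.1, 31.0, 36.0])
        result = count_threshold_days(daily)
        assert (result.hot_days, result.very_hot_days, result.extremely_hot_days) == (3, 2, 1)

    def test_night_counts(self):
        daily = make_daily([25.0, 25.0, 25.0], tmin=[18.5, 20.5, 17.0])
        result = count_threshold_days(daily)
        assert (result.warm_nights, result.tropical_nights) == (2, 1)

    def test_empty_input_gives_zeros(self):
        result = count_threshold_days(make_daily([]))
        assert result.hot_days == 0 and result.n_days == 0

    def test_incomplete_days_excluded_and_reported(self):
        daily = make_daily([31.0, 31.0])
        daily.loc[1, "complete"] = False
        result = count_threshold_days(daily)
        assert result.very_hot_days == 1 and result.n_excluded == 1

    def test_counts_nest(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            daily = make_daily(rng.uniform(15, 40, 30))
            r = count_threshold_days(daily)
            assert r.extremely_hot_days <= r.very_hot_days <= r.hot_days
            assert r.tropical_nights <= r.warm_nights


class TestDetectHeatWaves:
    def test_single_wave_at_front(self):
        waves = detect_heat_waves([31, 32, 33, 29, 31, 31])
        assert waves == [HeatWave(start=0, length=3)]

    def test_boundary_values_do_not_count(self):
        assert detect_heat_waves([30, 30, 30]) == []

    def test_whole_month_is_one_wave(self):
        waves = detect_heat_waves([31.0] * 30)
        assert waves == [HeatWave(start=0, length=30)]

    def test_waves_split_by_single_cool_day_stay_distinct(self):
        tmax = [31] * 4 + [29] + [31] * 3
        waves = detect_heat_waves(tmax)
        assert [(w.start, w.length) for w in waves] == [(0, 4), (5, 3)]

    def test_date_gap_is_an_error(self):
        dates = [pd.Timestamp("2019-06-01").date(), pd.Timestamp("2019-06-03").date(),
                 pd.Timestamp("2019-06-04").date()]
        with pytest.raises(ValueError, match="gap"):
            detect_heat_waves(pd.Series([31, 31, 31], index=dates))

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            values = rng.uniform(25, 35, rng.integers(1, 40))
            got = [(w.start, w.length) for w in detect_heat_waves(values)]
            assert got == brute_force_waves(values)


class TestAnomaly:
    def test_worked_example(self):
        # reference with mean 20 and sample SD exactly 2
        reference = [18.0, 20.0, 22.0, 18.0, 22.0, 20.0]
        sd = float(np.std(reference, ddof=1))
        result = anomaly(26.8, reference)
        assert result.absolute == pytest.approx(6.8)
        assert result.relative_sd == pytest.approx(6.8 / sd)

    def test_value_at_reference_mean_is_zero(self):
        result = anomaly(20.0, [19.0, 21.0])
        assert result.absolute == 0.0 and result.relative_sd == 0.0

    def test_constant_reference_keeps_absolute_only(self):
        result = anomaly(25.0, [20.0, 20.0, 20.0])
        assert result.absolute == 5.0
        assert np.isnan(result.relative_sd)

    def test_reference_too_short_rejected(self):
        with pytest.raises(ValueError):
            anomaly(25.0, [20.0])

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=-50, max_value=50, allow_nan=False))
    def test_location_equivariance(self, shift):
        reference = np.array([17.0, 19.5, 21.0, 23.5])
        base = anomaly(26.0, reference)
        shifted = anomaly(26.0 + shift, reference + shift)
        assert shifted.absolute == pytest.approx(base.absolute, abs=1e-9)
        assert shifted.relative_sd == pytest.approx(base.relative_sd, abs=1e-9)


class TestMonthlyMean:
    def test_worked_example(self):
        value, n = monthly_mean([61.3, 67.9, 65.1])
        assert value == pytest.approx(64.77, abs=0.005)
        assert n == 3

    def test_single_value(self):
        assert monthly_mean([12.5]) == (12.5, 1)

    def test_missing_values_skipped(self):
        value, n = monthly_mean([10.0, np.nan, 20.0])
        assert (value, n) == (15.0, 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            monthly_mean([np.nan])
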