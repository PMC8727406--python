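"""Heat-balance bookkeeping, heart rate, sultriness and daily budgets."""

import numpy as np
import pandas as pd
import pytest

from heatstrain.heat_strain import (
    DailyStrainBudget, FluxSet, PersonConfig,
    daily_budget, heart_rate, heat_balance, hourly_strain, max_evaporation,
    strain_day_table, sultriness_index, wind_at_1p2m,
)
from heatstrain.radiation import radiation_state
from heatstrain.synthetic import WeatherScenario, generate_weather
from heatstrain.utci import compute_utci


class TestHeartRate:
    def test_worked_values(self):
        assert heart_rate(135.0, 30.0, 20.0) == pytest.approx(97.5)
        assert heart_rate(135.0, 0.0, 0.0) == pytest.approx(46.7)
        # just over the circulatory warning level of 90 beats/min
        assert heart_rate(135.0, 25.0, 18.2) == pytest.approx(90.05, abs=0.005)
        assert heart_rate(135.0, 25.0, 18.2) > 90.0

    def test_exact_linear_increments(self):
        base = heart_rate(135.0, 22.0, 14.0)
        assert heart_rate(135.0, 23.0, 14.0) - base == pytest.approx(1.25, abs=1e-12)
        assert heart_rate(135.0, 22.0, 15.0) - base == pytest.approx(0.665, abs=1e-12)


class TestFluxSet:
    def test_sum_identity(self):
        fluxes = FluxSet(m=135.0, q=80.0, e=-120.0, c=-40.0, res=-10.0)
        assert fluxes.s == pytest.approx(45.0)

    def test_balanced_components_store_nothing(self):
        fluxes = FluxSet(m=135.0, q=20.0, e=-100.0, c=-45.0, res=-10.0)
        assert fluxes.s == pytest.approx(0.0)


class TestHeatBalance:
    def test_conservation_is_exact_by_construction(self):
        fluxes = heat_balance(ta=28.0, vp=18.0, v10=2.0, tmrt=45.0)
        assert fluxes.s == fluxes.m + fluxes.q + fluxes.e + fluxes.c + fluxes.res

    def test_loss_signs(self):
        fluxes = heat_balance(ta=25.0, vp=15.0, v10=3.0, tmrt=30.0)
        assert fluxes.e <= 0
        assert fluxes.res <= 0  # respiratory loss below 35 °C

    def test_hot_calm_noon_overheats(self):
        # clear noon, 33 °C, humid, near-calm: demand outruns Emax
        fluxes = heat_balance(ta=33.0, vp=22.0, v10=0.5, tmrt=60.0)
        assert fluxes.s > 15.0

    def test_mild_breezy_conditions_balance(self):
        fluxes = heat_balance(ta=24.0, vp=12.0, v10=3.0, tmrt=30.0)
        assert fluxes.s == pytest.approx(0.0, abs=1e-9)

    def test_wind_profile_factor(self):
        assert float(wind_at_1p2m(1.0)) == pytest.approx(0.693, abs=0.005)


class TestSultrinessIndex:
    def test_worked_value_is_fifty_percent(self):
        fluxes = FluxSet(m=135.0, q=0.0, e=0.0, c=-41.0, res=-10.0)  # Ereq = 84
        assert fluxes.ereq == pytest.approx(84.0)
        assert max_evaporation(7.0, 1.0, 16.0) == pytest.approx(168.0)
        assert sultriness_index(fluxes, v12=1.0, vp=16.0, k=7.0) == pytest.approx(50.0)

    def test_no_demand_means_zero(self):
        fluxes = FluxSet(m=135.0, q=-50.0, e=0.0, c=-80.0, res=-10.0)
        assert sultriness_index(fluxes, v12=1.0, vp=16.0, k=7.0) == 0.0

    def test_saturated_air_caps_at_hundred(self):
        fluxes = FluxSet(m=135.0, q=0.0, e=0.0, c=-41.0, res=-10.0)
        assert sultriness_index(fluxes, v12=1.0, vp=57.0, k=7.0) == 100.0

    def test_monotone_in_wind_and_humidity(self):
        fluxes = FluxSet(m=135.0, q=0.0, e=0.0, c=-41.0, res=-10.0)
        winds = np.arange(0.5, 5.1, 0.5)
        values = [sultriness_index(fluxes, v, 16.0, 7.0) for v in winds]
        assert all(a > b for a, b in zip(values, values[1:]))
        vps = np.arange(5.0, 50.0, 5.0)
        values = [sultriness_index(fluxes, 2.0, v, 7.0) for v in vps]
        assert all(a < b for a, b in zip(values, values[1:]))


class TestDailyBudget:
    def test_uniform_hot_day(self):
        budget = daily_budget([30.0] * 24, [0.0] * 24, [80.0] * 24, [0.0] * 24)
        assert budget.hst_hours == 24 and budget.hrt_hours == 0

    def test_mixed_day_counts(self):
        utci = [15.0] * 8 + [28.0] * 10 + [22.0] * 6
        budget = daily_budget(utci, [0.0] * 24, [80.0] * 24, [0.0] * 24)
        assert budget.hst_hours == 10 and budget.hrt_hours == 8

    def test_threshold_hour_is_strict(self):
        budget = daily_budget([26.0], [15.0], [90.0], [30.0])
        assert budget.hst_hours == 0
        assert budget.hours_s_gt15 == 0
        assert budget.hours_hr_gt90 == 0
        assert budget.hours_hsi_gt30 == 0

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            daily_budget([20.0] * 24, [0.0] * 23, [80.0] * 24, [0.0] * 24)

    def test_comfort_band_complement(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            utci = rng.uniform(10, 35, 24)
            budget = daily_budget(utci, np.zeros(24), np.zeros(24), np.zeros(24))
            comfort = int(((utci >= 18.0) & (utci <= 26.0)).sum())
            assert comfort == budget.valid_hours - budget.hst_hours - budget.hrt_hours

    def test_counts_match_brute_force_on_random_series(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            utci = rng.uniform(5, 45, 24)
            s = rng.uniform(-50, 60, 24)
            hr = rng.uniform(60, 110, 24)
            hsi = rng.uniform(0, 100, 24)
            budget = daily_budget(utci, s, hr, hsi)
            assert budget.hst_hours == sum(1 for u in utci if u > 26.0)
            assert budget.hrt_hours == sum(1 for u in utci if u < 18.0)
            assert budget.hours_s_gt15 == sum(1 for x in s if x > 15.0)
            assert budget.hours_hr_gt90 == sum(1 for x in hr if x > 90.0)
            assert budget.hours_hsi_gt30 == sum(1 for x in hsi if x > 30.0)

    def test_invariant_guard_rejects_impossible_counts(self):
        with pytest.raises(ValueError):
            DailyStrainBudget(date=None, hst_hours=20, hrt_hours=10,
                              hours_s_gt15=0, hours_hr_gt90=0,
                              hours_hsi_gt30=0, valid_hours=24)


def test_hourly_strain_conserves_on_synthetic_june():
    weather = generate_weather(WeatherScenario(seed=21))
    rad = radiation_state(52.2, 21.0, weather["timestamp"], weather["ta"],
                          weather["vp"], weather["cloud"])
    strain = hourly_strain(weather, rad["tmrt"].to_numpy())
    residual = strain["s"] - (strain["m"] + strain["q"] + strain["e"]
                              + strain["c"] + strain["res"])
    assert np.abs(residual).max() < 1e-12
    utci = compute_utci(weather["ta"], rad["tmrt"], weather["v10"], weather["vp"])
    budgets = strain_day_table(strain, utci)
    assert len(budgets) == 30
    assert (budgets["hst_hours"] + budgets["hrt_hours"] <= budgets["valid_hours"]).all()
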