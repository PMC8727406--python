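"""Synthetic June weather, pollution and mortality.

The generator emulates the statistical structure of a Central European June
at a lowland synoptic station, so that the whole analysis chain can be
exercised and validated without external archives:

* an hourly air-temperature cycle with its minimum near 04 and maximum near
  14 local solar time (two half-cosine branches, so both turning points sit
  where observed rather than 12 h apart),
* day-to-day variability as an AR(1) anomaly applied uniformly to all hours
  of a day (advection changes the whole day's level, not its diurnal shape),
* embedded multi-day heat-wave episodes that lift the affected days by a
  configured amplitude (so a +8 °C wave on a 26 °C-tmax background yields
  the >30 °C runs a heat-wave detector must find),
* humidity, wind and cloud covariates from positive-valued distributions
  around the scenario means, with vapour pressure kept below saturation,
* daily death counts from a Poisson baseline multiplied by a configurable
  relative risk on strong-heat-stress days.

Identical scenario + seed always yields bitwise-identical output; every
variable draws from its own deterministic sub-stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .station_io import HOURLY_COLUMNS
from .utci import HEAT_STRESS_CATEGORIES, saturation_vapour_pressure

_HOURS = np.arange(24)


@dataclass(frozen=True)
class WeatherScenario:
    """Parameters of one synthetic station-month.

    Defaults describe a warm Central European June (monthly mean ~20 °C,
    baseline tmax ~26 °C) with the two heat-wave windows of a severe year:
    days 10–16 and 25–27, both +8 °C, pushing tmax well above 30 °C.
    """

    latitude: float = 52.2
    longitude: float = 21.0
    days: int = 30
    base_mean_ta: float = 20.0
    diurnal_amplitude: float = 6.0   # half-range: tmax ≈ base + A, tmin ≈ base − A
    ar1_coefficient: float = 0.85
    noise_sd: float = 1.5            # SD of the AR(1) innovations, °C
    heat_wave_windows: tuple[tuple[int, int, float], ...] = ((10, 7, 8.0), (25, 3, 8.0))
    mean_vp: float = 15.0            # hPa
    mean_v10: float = 3.0            # m·s⁻¹
    mean_cloud: float = 0.4          # fraction
    seed: int = 0
    station_id: str = "SYN"
    year: int = 2019
    month: int = 6

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.noise_sd < 0 or self.diurnal_amplitude < 0:
            raise ValueError("noise_sd and diurnal_amplitude must be >= 0")
        for start, length, amplitude in self.heat_wave_windows:
            if length < 1:
                raise ValueError("heat-wave window length must be >= 1")
            if amplitude < 0:
                raise ValueError("heat-wave amplitude must be >= 0")
            if not (1 <= start and start + length - 1 <= self.days):
                raise ValueError("heat-wave window must lie within [1, days]")


@dataclass(frozen=True)
class MortalityScenario:
    """Poisson mortality with a multiplicative strong-heat relative risk."""

    population: int = 800_000
    baseline_daily_deaths: float = 30.0
    relative_risk: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_daily_deaths <= 0:
            raise ValueError("baseline_daily_deaths must be > 0")
        if self.relative_risk < 0:
            raise ValueError("relative_risk must be >= 0")


def _diurnal_shape(hour_local: np.ndarray) -> np.ndarray:
    """Unit diurnal cycle: −1 at 04, +1 at 14 local solar time, zero mean.

    Rising branch 04→14 and falling branch 14→04 (wrapping) are half-cosines,
    so the curve is continuous with turning points exactly at the observed
    extremes of a fair-weather summer day.
    """
    h = np.asarray(hour_local, dtype=float) % 24.0
    shape = np.empty_like(h)
    rising = (h >= 4.0) & (h < 14.0)
    shape[rising] = -np.cos(np.pi * (h[rising] - 4.0) / 10.0)
    falling = ~rising
    hf = (h[falling] - 14.0) % 24.0            # 0 .. 14 hours past the maximum
    shape[falling] = np.cos(np.pi * hf / 14.0)
    return shape


def day_level_offsets(scenario: WeatherScenario) -> np.ndarray:
    """Deterministic heat-wave offsets per day (before any noise), °C."""
    offsets = np.zeros(scenario.days)
    for start, length, amplitude in scenario.heat_wave_windows:
        offsets[start - 1:start - 1 + length] += amplitude
    return offsets


def generate_weather(scenario: WeatherScenario) -> pd.DataFrame:
    """Generate one month of hourly observations for one station.

    Returns an hourly frame in the shared ``HOURLY_COLUMNS`` layout with
    UTC timestamps; the diurnal cycle is phased by local solar time
    (longitude / 15°·h⁻¹), so at 21 °E the 14:00-local maximum falls near
    12:36 UTC.
    """
    ss = np.random.SeedSequence(scenario.seed)
    rng_ar1, rng_vp, rng_v10, rng_cloud = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    n_hours = scenario.days * 24
    day_index = np.repeat(np.arange(scenario.days), 24)
    hour_utc = np.tile(_HOURS, scenario.days)
    hour_local = (hour_utc + scenario.longitude / 15.0) % 24.0

    # AR(1) day-level anomaly, started from its stationary distribution
    phi, sd = scenario.ar1_coefficient, scenario.noise_sd
    anomaly = np.zeros(scenario.days)
    if sd > 0:
        innovations = rng_ar1.normal(0.0, sd, size=scenario.days)
        stationary_sd = sd / np.sqrt(1.0 - phi**2)
        anomaly[0] = rng_ar1.normal(0.0, stationary_sd)
        for d in range(1, scenario.days):
            anomaly[d] = phi * anomaly[d - 1] + innovations[d]

    ta = (
        scenario.base_mean_ta
        + scenario.diurnal_amplitude * _diurnal_shape(hour_local)
        + (anomaly + day_level_offsets(scenario))[day_index]
    )

    # vapour pressure: lognormal around the scenario mean, capped below saturation
    vp = rng_vp.lognormal(np.log(scenario.mean_vp) - 0.15**2 / 2, 0.15, n_hours)
    vp = np.minimum(vp, 0.97 * saturation_vapour_pressure(ta))
    vp = np.maximum(vp, 0.1)

    v10 = rng_v10.lognormal(np.log(scenario.mean_v10) - 0.4**2 / 2, 0.4, n_hours)

    # cloud fraction: Beta with the scenario mean and concentration 4
    a = 4.0 * scenario.mean_cloud
    b = 4.0 * (1.0 - scenario.mean_cloud)
    if a <= 0:
        cloud = np.zeros(n_hours)
    elif b <= 0:
        cloud = np.ones(n_hours)
    else:
        cloud = rng_cloud.beta(a, b, n_hours)

    start = pd.Timestamp(scenario.year, scenario.month, 1, tz="UTC")
    timestamps = start + pd.to_timedelta(np.arange(n_hours), unit="h")
    return pd.DataFrame(
        {
            "station_id": scenario.station_id,
            "timestamp": timestamps,
            "ta": ta,
            "vp": vp,
            "v10": v10,
            "cloud": cloud,
        }
    )[HOURLY_COLUMNS]


def generate_mortality(
    daily_categories, scenario: MortalityScenario
) -> np.ndarray:
    """Daily death counts: Poisson(baseline · RR^[strong-heat day]).

    ``daily_categories`` holds one thermal-stress category label per day;
    the relative risk applies on days whose label is a strong-heat category
    (SHS, VSHS or hotter).
    """
    categories = np.asarray(daily_categories, dtype=object)
    hot = np.isin(categories, list(HEAT_STRESS_CATEGORIES))
    lam = scenario.baseline_daily_deaths * np.where(hot, scenario.relative_risk, 1.0)
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    return rng.poisson(lam)


def generate_pollution(
    days: int, seed: int = 0, mean_pm25: float = 12.0, mean_o3: float = 65.0,
    station_id: str = "SYN", year: int = 2019, month: int = 6,
) -> pd.DataFrame:
    """Daily PM2.5 and O₃ concentrations around typical June means.

    Defaults match the reference-period June means observed at Polish
    monitoring networks (~12 µg·m⁻³ PM2.5, ~65 µg·m⁻³ O₃).
    """
    ss = np.random.SeedSequence(seed)
    rng_pm, rng_o3 = (np.random.default_rng(c) for c in ss.spawn(2))
    pm25 = rng_pm.lognormal(np.log(mean_pm25) - 0.25**2 / 2, 0.25, days)
    o3 = rng_o3.lognormal(np.log(mean_o3) - 0.15**2 / 2, 0.15, days)
    dates = pd.date_range(pd.Timestamp(year, month, 1), periods=days, freq="D").date
    return pd.DataFrame(
        {"station_id": station_id, "date": dates, "pm25": pm25, "o3": o3}
    )
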