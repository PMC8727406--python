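"""Solar geometry, global radiation under cloud, and mean radiant temperature.

The UTCI chain needs the mean radiant temperature (Tmrt), which synoptic
stations do not observe.  It is estimated here from what they do observe —
air temperature, vapour pressure and total cloud cover — through three
documented steps:

1. solar position from standard low-accuracy ephemeris formulas
   (Meeus/NOAA; adequate to a few tenths of a degree),
2. global irradiance from a one-parameter clear-sky transmittance model
   attenuated by the Kasten–Czeplak cloud factor 1 − 0.75·N^3.4,
3. Tmrt of a standing person from absorbed short-wave radiation plus
   hemispheric sky and ground long-wave exchange, with a Brunt-type sky
   emissivity in vapour pressure and a linear cloud correction.

All empirical constants live in :class:`RadiationConstants` so a run can
log them into its metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

SIGMA = 5.670374419e-8  # Stefan–Boltzmann constant, W·m⁻²·K⁻⁴


@dataclass(frozen=True)
class RadiationConstants:
    """Empirical constants of the radiation/Tmrt chain (one config block).

    Attributes
    ----------
    solar_constant
        Top-of-atmosphere irradiance, W·m⁻².
    clear_sky_transmittance
        Bulk atmospheric transmittance at unit air mass; irradiance is
        S₀·τ^(1/sin h)·sin h.  0.75 suits an aerosol-free rural summer
        atmosphere (no aerosol data is available in the inputs).
    cloud_attenuation_scale, cloud_attenuation_power
        Kasten–Czeplak total-cloud attenuation 1 − a·N^b.
    brunt_intercept, brunt_slope
        Clear-sky emissivity ε₀ = a + b·√vp (vp in hPa).
    person_albedo
        Short-wave reflectance of a clothed person.
    projected_area_factor
        Fraction of global irradiance intercepted per unit body surface
        for a standing person (solid-angle average).
    body_emissivity
        Long-wave emissivity of the body surface.
    """

    solar_constant: float = 1361.0
    clear_sky_transmittance: float = 0.75
    cloud_attenuation_scale: float = 0.75
    cloud_attenuation_power: float = 3.4
    brunt_intercept: float = 0.52
    brunt_slope: float = 0.065
    person_albedo: float = 0.3
    projected_area_factor: float = 0.25
    body_emissivity: float = 0.97

    def as_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONSTANTS = RadiationConstants()


def _julian_day(timestamp: pd.DatetimeIndex) -> np.ndarray:
    """Julian day number (UTC) including the day fraction."""
    ts = pd.DatetimeIndex(timestamp).tz_convert("UTC")
    epoch = pd.Timestamp("2000-01-01T12:00:00", tz="UTC")  # J2000.0 = JD 2451545.0
    delta_days = (ts - epoch) / pd.Timedelta(days=1)
    return 2451545.0 + np.asarray(delta_days, dtype=float)


def solar_position(latitude: float, longitude: float, timestamp) -> tuple[np.ndarray, np.ndarray]:
    """Solar elevation and azimuth (degrees) at the given UTC instant(s).

    Uses the NOAA general solar-position formulas (truncated Meeus series);
    atmospheric refraction is not applied.  Azimuth is measured clockwise
    from north.
    """
    if not abs(latitude) <= 90:
        raise ValueError("latitude must lie in [-90, 90]")
    scalar = not isinstance(timestamp, (pd.DatetimeIndex, list, np.ndarray, pd.Series))
    index = pd.DatetimeIndex([timestamp] if scalar else timestamp)
    if index.tz is None:
        index = index.tz_localize("UTC")

    jd = _julian_day(index)
    t = (jd - 2451545.0) / 36525.0  # Julian centuries since J2000

    geom_mean_long = np.mod(280.46646 + t * (36000.76983 + 0.0003032 * t), 360.0)
    geom_mean_anom = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    m = np.radians(geom_mean_anom)
    eq_center = (
        np.sin(m) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + np.sin(2 * m) * (0.019993 - 0.000101 * t)
        + np.sin(3 * m) * 0.000289
    )
    true_long = geom_mean_long + eq_center
    omega = np.radians(125.04 - 1934.136 * t)
    app_long = np.radians(true_long - 0.00569 - 0.00478 * np.sin(omega))

    mean_obliq = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    obliq = np.radians(mean_obliq + 0.00256 * np.cos(omega))

    declination = np.arcsin(np.sin(obliq) * np.sin(app_long))

    y = np.tan(obliq / 2.0) ** 2
    l0 = np.radians(geom_mean_long)
    eq_time = 4.0 * np.degrees(
        y * np.sin(2 * l0)
        - 2.0 * ecc * np.sin(m)
        + 4.0 * ecc * y * np.sin(m) * np.cos(2 * l0)
        - 0.5 * y * y * np.sin(4 * l0)
        - 1.25 * ecc * ecc * np.sin(2 * m)
    )  # minutes

    minutes_utc = index.hour * 60.0 + index.minute + index.second / 60.0
    true_solar_minutes = np.mod(minutes_utc + eq_time + 4.0 * longitude, 1440.0)
    hour_angle = np.radians(true_solar_minutes / 4.0 - 180.0)

    lat = np.radians(latitude)
    sin_elev = (
        np.sin(lat) * np.sin(declination)
        + np.cos(lat) * np.cos(declination) * np.cos(hour_angle)
    )
    elevation = np.degrees(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))

    zenith = np.radians(90.0 - elevation)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_az = (np.sin(lat) * np.cos(zenith) - np.sin(declination)) / (
            np.cos(lat) * np.sin(zenith)
        )
    azimuth_raw = np.degrees(np.arccos(np.clip(cos_az, -1.0, 1.0)))
    azimuth = np.where(hour_angle > 0, np.mod(azimuth_raw + 180.0, 360.0),
                       np.mod(180.0 - azimuth_raw, 360.0))
    azimuth = np.where(np.isfinite(azimuth), azimuth, 0.0)

    if scalar:
        return float(elevation[0]), float(azimuth[0])
    return elevation, azimuth


def clear_sky_irradiance(
    elevation, constants: RadiationConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """Cloudless global irradiance (W·m⁻²) for a given solar elevation.

    One-parameter bulk-transmittance model S₀·τ^(1/sin h)·sin h; zero at
    and below the horizon.
    """
    h = np.radians(np.asarray(elevation, dtype=float))
    sin_h = np.sin(h)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        irradiance = np.where(
            sin_h > 0,
            constants.solar_constant
            * constants.clear_sky_transmittance ** (1.0 / np.maximum(sin_h, 1e-9))
            * sin_h,
            0.0,
        )
    return irradiance


def cloud_transmission(cloud, constants: RadiationConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Kasten–Czeplak attenuation factor 1 − a·N^b for total cloud cover N."""
    n = np.asarray(cloud, dtype=float)
    if np.any((n < 0) | (n > 1)):
        raise ValueError("cloud cover must lie in [0, 1]")
    return 1.0 - constants.cloud_attenuation_scale * n ** constants.cloud_attenuation_power


def global_radiation(
    elevation, cloud, constants: RadiationConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """All-sky global irradiance (W·m⁻²): clear sky times the cloud factor."""
    return clear_sky_irradiance(elevation, constants) * cloud_transmission(cloud, constants)


def sky_emissivity(vp, cloud, constants: RadiationConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Effective sky emissivity: Brunt clear-sky term, linear in cloud to 1.

    ε = ε₀ + (1 − ε₀)·N with ε₀ = a + b·√vp, clipped to [0, 1], so a fully
    overcast sky radiates as a black body at air temperature.
    """
    eps_clear = np.clip(
        constants.brunt_intercept + constants.brunt_slope * np.sqrt(np.asarray(vp, float)),
        0.0, 1.0,
    )
    return eps_clear + (1.0 - eps_clear) * np.asarray(cloud, dtype=float)


def mean_radiant_temp(
    ta, vp, cloud, kglob, elevation,
    constants: RadiationConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Mean radiant temperature (°C) of a standing person outdoors.

    The radiant environment is split into the upper hemisphere (sky at air
    temperature with the cloud/humidity-dependent emissivity) and the lower
    hemisphere (ground treated as a black body at air temperature), plus the
    absorbed short-wave load (1 − albedo)·f_p·K_glob spread over the body
    surface.  Solving σ·T_mrt⁴ = long-wave + short-wave/ε_p gives Tmrt.

    At night under overcast sky this collapses to Tmrt = ta (the enclosure
    limit); clear skies pull Tmrt below ta, sunshine far above it.
    """
    ta_k = np.asarray(ta, dtype=float) + 273.15
    kglob = np.asarray(kglob, dtype=float)
    eps_sky = sky_emissivity(vp, cloud, constants)

    l_sky = eps_sky * SIGMA * ta_k**4
    l_ground = SIGMA * ta_k**4
    shortwave = (
        (1.0 - constants.person_albedo)
        * constants.projected_area_factor
        * np.where(np.asarray(elevation, dtype=float) > 0, kglob, 0.0)
        / constants.body_emissivity
    )
    tmrt_k = ((0.5 * l_sky + 0.5 * l_ground + shortwave) / SIGMA) ** 0.25
    return tmrt_k - 273.15


def radiation_state(
    latitude: float, longitude: float, timestamps, ta, vp, cloud,
    constants: RadiationConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Full radiation chain for an hourly series.

    Returns a frame aligned with the inputs holding solar elevation and
    azimuth (°), global irradiance ``kglob`` (W·m⁻²), the net long-wave
    exchange ``lnet`` of the environment relative to air temperature
    (W·m⁻², negative under clear sky), and ``tmrt`` (°C).
    """
    elevation, azimuth = solar_position(latitude, longitude, timestamps)
    kglob = global_radiation(elevation, cloud, constants)
    ta_k = np.asarray(ta, dtype=float) + 273.15
    lnet = (0.5 * sky_emissivity(vp, cloud, constants) + 0.5 - 1.0) * SIGMA * ta_k**4
    tmrt = mean_radiant_temp(ta, vp, cloud, kglob, elevation, constants)
    return pd.DataFrame(
        {
            "solar_elevation": elevation,
            "solar_azimuth": azimuth,
            "kglob": kglob,
            "lnet": lnet,
            "tmrt": tmrt,
        }
    )
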