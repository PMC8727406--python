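"""Physiological heat-strain measures for a person outdoors.

The package follows the classical outdoor heat-balance bookkeeping: for a
reference person (walking at 4 km·h⁻¹, metabolic rate M = 135 W·m⁻²) every
flux is expressed per unit body surface with gains positive and losses
negative, and the net heat storage

    S = M + Q + E + C + Res            (W·m⁻²)

is the residual of metabolic heat M, the radiation balance Q (absorbed
short-wave plus net long-wave on the body), evaporative loss E, convective
exchange C and respiratory loss Res.  Sustained S above +15 W·m⁻²
indicates a risk of overheating (roughly +2 °C core temperature after 3 h
of accumulation).

Companion indices:

* heart rate  HR = 22.4 + 0.18·M + 0.25·(5·ta + 2.66·vp)  [beats·min⁻¹],
  with 90 beats·min⁻¹ as the circulatory warning level;
* sultriness index  HSI = 100·Ereq/Emax  [%], the evaporation required for
  equilibrium (Ereq = M + Q + C + Res) as a share of the evaporation the
  air can absorb, Emax = k·v·0.6·(56 − vp) with wind v at 1.2 m and
  k = 7.0 clothed / 11.7 naked; HSI > 30 % marks intensive sultriness;
* daily hour budgets: heat-stress time HST (UTCI > 26 °C), heat-recovery
  time HRT (UTCI < 18 °C), and hours with S > 15, HR > 90, HSI > 30.

The exact internal formulations of the original heat-balance software are
not published; the skin-temperature, convection and respiration closures
used here are standard documented forms whose constants live in
:class:`StrainConstants` and are echoed into run metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .radiation import SIGMA

#: warning thresholds (config defaults, overridable)
S_OVERHEAT_THRESHOLD = 15.0       # W·m⁻²
HR_WARNING_THRESHOLD = 90.0       # beats·min⁻¹
HSI_WARNING_THRESHOLD = 30.0      # %
HST_UTCI_THRESHOLD = 26.0         # °C, heat-stress time above this
HRT_UTCI_THRESHOLD = 18.0         # °C, heat-recovery time below this
#: hours of sustained S > 15 W·m⁻² after which core temperature may have
#: risen by about 2 °C (static annotation, not simulated)
SUSTAINED_OVERHEAT_HOURS = 3


@dataclass(frozen=True)
class StrainConstants:
    """Documented closure constants of the heat-balance implementation."""

    roughness_length: float = 0.01        # m, for the 10 m -> 1.2 m wind profile
    hc_scale: float = 8.3                 # W·m⁻²·K⁻¹ per (m·s⁻¹)^hc_power
    hc_power: float = 0.6
    hc_floor: float = 3.0                 # free-convection minimum
    clothing_transfer: float = 0.6        # flux reduction by clothing
    body_emissivity: float = 0.97
    radiating_area_fraction: float = 0.71  # effective radiating body fraction
    # empirical linear skin temperature: tsk = a + b·ta + c·tmrt + d·(M−135)
    skin_intercept: float = 26.4
    skin_ta_slope: float = 0.18
    skin_tmrt_slope: float = 0.04
    skin_met_slope: float = 0.01
    skin_cap: float = 36.5

    def as_dict(self) -> dict:
        return asdict(self)


DEFAULT_STRAIN_CONSTANTS = StrainConstants()


@dataclass(frozen=True)
class PersonConfig:
    """Reference person of the analysis.

    The default metabolic rate (135 W·m⁻²) is typical for walking at
    4 km·h⁻¹; clothing selects the evaporation coefficient k of the
    sultriness index (7.0 clothed, 11.7 naked).
    """

    metabolic_rate: float = 135.0
    clothed: bool = True
    albedo: float = 0.3

    def __post_init__(self) -> None:
        if self.metabolic_rate <= 0:
            raise ValueError("metabolic rate must be positive")

    @property
    def evaporation_coefficient(self) -> float:
        return 7.0 if self.clothed else 11.7


@dataclass(frozen=True)
class FluxSet:
    """Heat-balance components for one exposure hour (W·m⁻²).

    Gains are positive, losses negative; ``s`` is always the exact sum
    M + Q + E + C + Res.
    """

    m: float
    q: float
    e: float
    c: float
    res: float
    skin_temperature: float = float("nan")

    @property
    def s(self) -> float:
        return self.m + self.q + self.e + self.c + self.res

    @property
    def ereq(self) -> float:
        """Evaporation required for equilibrium (non-evaporative net gain)."""
        return self.m + self.q + self.c + self.res


@dataclass(frozen=True)
class DailyStrainBudget:
    """Per-day hour counts of the strain measures."""

    date: object
    hst_hours: int
    hrt_hours: int
    hours_s_gt15: int
    hours_hr_gt90: int
    hours_hsi_gt30: int
    valid_hours: int
    sustained_overheating: bool = False

    def __post_init__(self) -> None:
        counts = (self.hst_hours, self.hrt_hours, self.hours_s_gt15,
                  self.hours_hr_gt90, self.hours_hsi_gt30)
        if any(c < 0 or c > self.valid_hours for c in counts):
            raise ValueError("hour counts must lie in [0, valid_hours]")
        if self.hst_hours + self.hrt_hours > self.valid_hours:
            raise ValueError("HST + HRT cannot exceed the valid hours")


def heart_rate(metabolic_rate, ta, vp):
    """Heart rate (beats·min⁻¹) from metabolism, air temperature and humidity.

    HR = 22.4 + 0.18·M + 0.25·(5·ta + 2.66·vp); exactly linear with
    increments 1.25 per °C and 0.665 per hPa.
    """
    m = np.asarray(metabolic_rate, dtype=float)
    return 22.4 + 0.18 * m + 0.25 * (5.0 * np.asarray(ta, float)
                                     + 2.66 * np.asarray(vp, float))


def wind_at_1p2m(v10, constants: StrainConstants = DEFAULT_STRAIN_CONSTANTS):
    """Wind at 1.2 m from the 10-m value via a neutral logarithmic profile.

    With roughness length 0.01 m the reduction factor is
    ln(1.2/z0)/ln(10/z0) ≈ 0.69.
    """
    factor = np.log(1.2 / constants.roughness_length) / np.log(10.0 / constants.roughness_length)
    return np.asarray(v10, dtype=float) * factor


def skin_temperature(
    ta, tmrt, metabolic_rate,
    constants: StrainConstants = DEFAULT_STRAIN_CONSTANTS,
):
    """Empirical mean skin temperature (°C), linear in ta, Tmrt and M."""
    tsk = (
        constants.skin_intercept
        + constants.skin_ta_slope * np.asarray(ta, float)
        + constants.skin_tmrt_slope * np.asarray(tmrt, float)
        + constants.skin_met_slope * (np.asarray(metabolic_rate, float) - 135.0)
    )
    return np.minimum(tsk, constants.skin_cap)


def max_evaporation(k, v12, vp):
    """Evaporative capacity of the air, Emax = k·v·0.6·(56 − vp) (W·m⁻²).

    Negative once vp exceeds 56 hPa: saturated air absorbs no sweat.
    """
    return np.asarray(k, float) * np.asarray(v12, float) * 0.6 * (56.0 - np.asarray(vp, float))


def heat_balance(
    ta: float, vp: float, v10: float, tmrt: float,
    person: PersonConfig = PersonConfig(),
    constants: StrainConstants = DEFAULT_STRAIN_CONSTANTS,
) -> FluxSet:
    """Resolve the heat balance of one exposure hour into a :class:`FluxSet`.

    Q is the radiant exchange between the body surface and an environment
    at Tmrt; C a power-law forced-convection exchange at 1.2-m wind; Res
    the standard respiratory loss in ta and vp (clipped to a loss); E the
    evaporation required for equilibrium, realisable at most up to Emax.
    Whatever demand Emax cannot absorb remains as positive net storage S.
    """
    m = person.metabolic_rate
    v12 = float(wind_at_1p2m(v10, constants))
    tsk = float(skin_temperature(ta, tmrt, m, constants))

    fcl = constants.clothing_transfer if person.clothed else 1.0
    q = fcl * constants.body_emissivity * constants.radiating_area_fraction * SIGMA * (
        (tmrt + 273.15) ** 4 - (tsk + 273.15) ** 4
    )
    hc = max(constants.hc_scale * v12 ** constants.hc_power, constants.hc_floor)
    c = fcl * hc * (ta - tsk)
    res = -max(0.0, 0.0014 * m * (34.0 - ta) + 1.72e-5 * m * (5867.0 - 100.0 * vp))

    ereq = m + q + c + res
    emax = float(max_evaporation(person.evaporation_coefficient, v12, vp))
    e = -float(np.clip(ereq, 0.0, max(emax, 0.0)))

    return FluxSet(m=m, q=q, e=e, c=c, res=res, skin_temperature=tsk)


def sultriness_index(fluxes: FluxSet, v12: float, vp: float, k: float) -> float:
    """Sultriness index HSI (%) for a resolved flux set.

    HSI = 100·Ereq/Emax, floored at 0 when no evaporation is required and
    capped at 100 when the demand reaches (or the air cannot absorb) the
    evaporative capacity.
    """
    ereq = fluxes.ereq
    if ereq <= 0:
        return 0.0
    emax = float(max_evaporation(k, v12, vp))
    if emax <= 0:
        return 100.0
    return float(min(100.0 * ereq / emax, 100.0))


def daily_budget(
    hourly_utci, hourly_s, hourly_hr, hourly_hsi, date=None,
) -> DailyStrainBudget:
    """Count threshold hours (strict inequalities) for one aligned day."""
    utci = np.asarray(hourly_utci, dtype=float)
    s = np.asarray(hourly_s, dtype=float)
    hr = np.asarray(hourly_hr, dtype=float)
    hsi = np.asarray(hourly_hsi, dtype=float)
    if not (utci.shape == s.shape == hr.shape == hsi.shape):
        raise ValueError("hourly series are misaligned")
    overheat = s > S_OVERHEAT_THRESHOLD
    return DailyStrainBudget(
        date=date,
        hst_hours=int((utci > HST_UTCI_THRESHOLD).sum()),
        hrt_hours=int((utci < HRT_UTCI_THRESHOLD).sum()),
        hours_s_gt15=int(overheat.sum()),
        hours_hr_gt90=int((hr > HR_WARNING_THRESHOLD).sum()),
        hours_hsi_gt30=int((hsi > HSI_WARNING_THRESHOLD).sum()),
        valid_hours=int(len(utci)),
        sustained_overheating=bool(_longest_run(overheat) >= SUSTAINED_OVERHEAT_HOURS),
    )


def _longest_run(mask: np.ndarray) -> int:
    longest = current = 0
    for flag in mask:
        current = current + 1 if flag else 0
        longest = max(longest, current)
    return longest


def hourly_strain(
    obs: pd.DataFrame, tmrt, person: PersonConfig = PersonConfig(),
    constants: StrainConstants = DEFAULT_STRAIN_CONSTANTS,
) -> pd.DataFrame:
    """Heat-balance fluxes, HR and HSI for every row of an hourly frame."""
    tmrt = np.asarray(tmrt, dtype=float)
    if tmrt.shape != (len(obs),):
        raise ValueError("tmrt must align row-for-row with the observations")
    records = []
    k = person.evaporation_coefficient
    for row, row_tmrt in zip(obs.itertuples(index=False), tmrt):
        fluxes = heat_balance(row.ta, row.vp, row.v10, row_tmrt, person, constants)
        v12 = float(wind_at_1p2m(row.v10, constants))
        records.append(
            {
                "station_id": row.station_id,
                "timestamp": row.timestamp,
                "m": fluxes.m, "q": fluxes.q, "e": fluxes.e,
                "c": fluxes.c, "res": fluxes.res, "s": fluxes.s,
                "skin_temperature": fluxes.skin_temperature,
                "hr": float(heart_rate(person.metabolic_rate, row.ta, row.vp)),
                "hsi": sultriness_index(fluxes, v12, row.vp, k),
            }
        )
    return pd.DataFrame(records)


def strain_day_table(strain: pd.DataFrame, utci) -> pd.DataFrame:
    """Daily strain budgets from an hourly strain frame plus aligned UTCI."""
    utci = np.asarray(utci, dtype=float)
    if utci.shape != (len(strain),):
        raise ValueError("utci must align row-for-row with the strain frame")
    work = strain.copy()
    work["utci"] = utci
    work["date"] = pd.DatetimeIndex(work["timestamp"]).tz_convert("UTC").date
    rows = []
    for (station, date), day in work.groupby(["station_id", "date"], sort=True):
        budget = daily_budget(day["utci"], day["s"], day["hr"], day["hsi"], date=date)
        rows.append(
            {
                "station_id": station,
                "date": date,
                "hst_hours": budget.hst_hours,
                "hrt_hours": budget.hrt_hours,
                "hours_s_gt15": budget.hours_s_gt15,
                "hours_hr_gt90": budget.hours_hr_gt90,
                "hours_hsi_gt30": budget.hours_hsi_gt30,
                "valid_hours": budget.valid_hours,
                "sustained_overheating": budget.sustained_overheating,
            }
        )
    return pd.DataFrame(rows)
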