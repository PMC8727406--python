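"""Heat-related mortality measures and an effect-recovery estimator.

Two observational measures and one model-based measure are implemented for
monthly (default June) all-cause mortality:

* TMrel — a month's death count as a percentage of the reference-period
  mean for the same month:  TMrel = 100·TMx/TMavg.  By construction the
  reference years' TMrel values average exactly 100.
* SHRM — deaths attributable to strong heat, modelled as linear in the
  city's population rate (per 100 000 inhabitants) and in the number of
  strong-heat days:  SHRM = 2.595·PopRate·(SHS + VSHS), where SHS/VSHS
  count days in the strong (UTCI 32.1–38 °C) and very strong (> 38 °C)
  heat-stress categories.  The 2.595 coefficient is adopted verbatim from
  the published model; SHRM is reported as model-attributed deaths per
  month.
* SHRMrel — SHRM as a percentage of the reference-period mean SHRM.

For validation on synthetic data, :func:`estimate_heat_effect` recovers
the relative risk of death on strong-heat days as a ratio of stratum means
with a stratified percentile-bootstrap interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .utci import HEAT_STRESS_CATEGORIES

SHRM_COEFFICIENT = 2.595  # expected deaths per strong-heat day per 100 000


@dataclass(frozen=True)
class CityMortality:
    """Monthly mortality bookkeeping for one city."""

    city_id: str
    population: int
    monthly_deaths: float
    reference_mean_deaths: float
    shs_days: int
    vshs_days: int

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError("population must be positive")
        if self.shs_days < 0 or self.vshs_days < 0:
            raise ValueError("stress-day counts must be >= 0")

    @property
    def pop_rate(self) -> float:
        """Population per 100 000 inhabitants."""
        return self.population / 100_000.0

    @property
    def tm_rel(self) -> float:
        return tm_rel(self.monthly_deaths, self.reference_mean_deaths)

    @property
    def shrm(self) -> float:
        return shrm(self.pop_rate, self.shs_days, self.vshs_days)


@dataclass(frozen=True)
class HeatEffectEstimate:
    """Relative-risk estimate with a percentile bootstrap interval."""

    relative_risk: float
    ci_low: float
    ci_high: float
    n_stress_days: int
    n_other_days: int


def tm_rel(tmx: float, tmavg: float) -> float:
    """Relative monthly mortality (%), 100·TMx/TMavg."""
    if not tmavg > 0:
        raise ValueError("reference mean mortality must be positive")
    return 100.0 * tmx / tmavg


def shrm(pop_rate: float, shs_days: float, vshs_days: float) -> float:
    """Model-attributed monthly deaths from strong heat.

    ``pop_rate`` is population per 100 000; ``shs_days``/``vshs_days`` the
    month's strong and very strong heat-stress day counts.
    """
    if pop_rate < 0 or shs_days < 0 or vshs_days < 0:
        raise ValueError("inputs must be >= 0")
    return SHRM_COEFFICIENT * pop_rate * (shs_days + vshs_days)


def shrm_rel(shrm_value: float, reference_mean_shrm: float) -> float:
    """SHRM as a percentage of the reference-period mean SHRM."""
    if not reference_mean_shrm > 0:
        raise ValueError("reference mean SHRM must be positive")
    return 100.0 * shrm_value / reference_mean_shrm


def reference_mean(values) -> float:
    """Mean over the non-missing reference-year values (never imputed)."""
    series = pd.Series(values).dropna()
    if len(series) == 0:
        raise ValueError("no valid reference values")
    return float(series.mean())


def count_stress_days(daily_categories) -> tuple[int, int]:
    """Count (SHS, VSHS-or-hotter) days from per-day category labels."""
    cats = np.asarray(daily_categories, dtype=object)
    shs = int((cats == "SHS").sum())
    vshs = int(np.isin(cats, ["VSHS", "above scale"]).sum())
    return shs, vshs


def estimate_heat_effect(
    daily_deaths,
    daily_categories,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> HeatEffectEstimate:
    """Recover the strong-heat relative risk from daily deaths and categories.

    RR is the ratio of mean deaths on strong-heat days (SHS and hotter) to
    mean deaths on all other days; the interval is a stratified percentile
    bootstrap over days (each stratum resampled with replacement), so no
    resample can lose a stratum.

    Raises
    ------
    ValueError
        If either stratum is empty — the contrast is undefined then.
    """
    deaths = np.asarray(daily_deaths, dtype=float)
    cats = np.asarray(daily_categories, dtype=object)
    if deaths.shape != cats.shape:
        raise ValueError("deaths and categories are misaligned")
    hot = np.isin(cats, list(HEAT_STRESS_CATEGORIES))
    hot_deaths, other_deaths = deaths[hot], deaths[~hot]
    if len(hot_deaths) == 0 or len(other_deaths) == 0:
        raise ValueError("need at least one strong-heat day and one other day")

    rr = hot_deaths.mean() / other_deaths.mean()

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        hs = rng.choice(hot_deaths, size=len(hot_deaths), replace=True)
        os_ = rng.choice(other_deaths, size=len(other_deaths), replace=True)
        boot[b] = hs.mean() / os_.mean() if os_.mean() > 0 else np.nan
    boot = boot[np.isfinite(boot)]
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])

    return HeatEffectEstimate(
        relative_risk=float(rr), ci_low=float(lo), ci_high=float(hi),
        n_stress_days=int(hot.sum()), n_other_days=int((~hot).sum()),
    )


def load_published_june_table() -> pd.DataFrame:
    """The published national June indicator table for Poland, 2010–2019.

    One row per year (plus the printed 2010–2018 reference-mean row),
    holding relative mortality (TMrel, SHRMrel), the mean monthly midday
    UTCI, strong-heat day counts, and O₃/PM2.5 means with their relative
    values.  TMrel is missing for 2011 and 2014 in the source and stays
    missing here.
    """
    with resources.files("heatstrain.data").joinpath(
        "poland_june_2010_2019.csv"
    ).open("rb") as handle:
        return pd.read_csv(handle, dtype={"period": str})
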