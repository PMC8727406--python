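"""End-to-end orchestration: weather → UTCI → indicators → strain → mortality.

A single declarative :class:`RunConfig` drives the whole chain, either from
synthetic scenarios (the default demonstration mode: one analysis June with
heat waves against a set of reference Junes) or from user-supplied station
files.  Every stage writes its intermediate table into the output
directory, and the final report is assembled strictly from those cached
files, so any stage can be re-run in isolation.  Runs are deterministic:
identical config + seed produce byte-identical output bundles, and the run
metadata records the config hash, the seed and every empirical constant.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import station_io
from .climatology import anomaly, count_threshold_days, detect_heat_waves
from .heat_strain import (
    DEFAULT_STRAIN_CONSTANTS, HR_WARNING_THRESHOLD, HRT_UTCI_THRESHOLD,
    HSI_WARNING_THRESHOLD, HST_UTCI_THRESHOLD, PersonConfig,
    S_OVERHEAT_THRESHOLD, StrainConstants, hourly_strain, strain_day_table,
)
from .mortality import reference_mean, shrm, shrm_rel, tm_rel
from .radiation import DEFAULT_CONSTANTS, RadiationConstants, radiation_state
from .synthetic import (
    MortalityScenario, WeatherScenario, generate_mortality,
    generate_pollution, generate_weather,
)
from .utci import (
    UTCI_COEFFICIENT_SHA256, UTCI_COEFFICIENT_VERSION, classify_stress,
    compute_utci,
)

logger = logging.getLogger("heatstrain")

_REFERENCE_LABEL = "ref_mean"


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one analysis run.

    In synthetic mode (the default) the analysis year is generated from
    ``scenario`` and every reference year from ``reference_scenario``
    (identical background climate, no embedded heat waves), each with a
    deterministic per-year seed derived from the run seed.
    """

    seed: int = 0
    outdir: str = "heatstrain_run"
    analysis_year: int = 2019
    reference_years: tuple[int, ...] = tuple(range(2010, 2019))
    month: int = 6
    #: which daily UTCI statistic a day's stress category is read from
    day_category_basis: str = "utci_max_12"
    midday_hour: int = 12
    min_valid_hours: int = station_io.DEFAULT_MIN_VALID_HOURS
    scenario: WeatherScenario = field(default_factory=WeatherScenario)
    #: climatological June: cooler, cloudier and windier than the hot year,
    #: with one short warm spell instead of embedded heat waves
    reference_scenario: WeatherScenario = field(
        default_factory=lambda: WeatherScenario(
            base_mean_ta=16.5, diurnal_amplitude=5.0, mean_cloud=0.65,
            mean_v10=4.0, heat_wave_windows=((12, 3, 10.0),),
        )
    )
    mortality_scenario: MortalityScenario = field(default_factory=MortalityScenario)
    person: PersonConfig = field(default_factory=PersonConfig)
    radiation_constants: RadiationConstants = DEFAULT_CONSTANTS
    strain_constants: StrainConstants = DEFAULT_STRAIN_CONSTANTS

    def __post_init__(self) -> None:
        if not self.reference_years:
            raise ValueError("reference period must be non-empty")
        if self.day_category_basis not in ("utci_max_12", "utci_avg_12", "utci_max"):
            raise ValueError(f"unknown day_category_basis {self.day_category_basis!r}")

    @property
    def years(self) -> list[int]:
        return [*self.reference_years, self.analysis_year]

    def year_seed(self, year: int, stream: int = 0) -> int:
        """Deterministic sub-seed (< 2³¹) for one year and variable stream."""
        state = np.random.SeedSequence([self.seed, year, stream]).generate_state(1)[0]
        return int(state % (2**31))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output location is a
        runtime detail and does not participate)."""
        payload = _plain(self.to_dict())
        payload.pop("outdir", None)
        canonical = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, factory in (
            ("scenario", WeatherScenario),
            ("reference_scenario", WeatherScenario),
            ("mortality_scenario", MortalityScenario),
            ("person", PersonConfig),
            ("radiation_constants", RadiationConstants),
            ("strain_constants", StrainConstants),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                if "heat_wave_windows" in sub:
                    sub["heat_wave_windows"] = tuple(
                        tuple(w) for w in sub["heat_wave_windows"]
                    )
                kwargs[key] = factory(**sub)
        if "reference_years" in kwargs:
            kwargs["reference_years"] = tuple(kwargs["reference_years"])
        return cls(**kwargs)


def _plain(obj):
    """Recursively convert to YAML/JSON-serialisable builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class ReportBundle:
    """Assembled outputs of one run."""

    outdir: Path
    aggregates: pd.DataFrame
    table1: pd.DataFrame
    indicators: pd.DataFrame
    metadata: dict


# ---------------------------------------------------------------------------
# stages (each reads/writes cached files in the output directory)
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> None:
    """Generate hourly weather files for every year of the run."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for year in config.years:
        template = (
            config.scenario if year == config.analysis_year else config.reference_scenario
        )
        scenario = replace(
            template, seed=config.year_seed(year, 0), year=year, month=config.month
        )
        weather = generate_weather(scenario)
        station_io.write_hourly(weather, outdir / f"hourly_{year}.csv")
        logger.info("simulate: %d -> %d hourly records", year, len(weather))


def stage_utci(config: RunConfig) -> None:
    """Radiation + UTCI chain: hourly_*.csv -> utci_*.csv and daily_*.csv."""
    outdir = Path(config.outdir)
    for year in config.years:
        obs = station_io.read_hourly(outdir / f"hourly_{year}.csv")
        scenario = config.scenario if year == config.analysis_year else config.reference_scenario
        rad = radiation_state(
            scenario.latitude, scenario.longitude, obs["timestamp"],
            obs["ta"], obs["vp"], obs["cloud"], config.radiation_constants,
        )
        utci, clamped = compute_utci(
            obs["ta"], rad["tmrt"], obs["v10"], obs["vp"], return_flags=True
        )
        utci = np.atleast_1d(utci)
        hourly = obs[["station_id", "timestamp"]].copy()
        hourly["tmrt"] = rad["tmrt"].to_numpy()
        hourly["kglob"] = rad["kglob"].to_numpy()
        hourly["utci"] = utci
        hourly["clamped"] = np.atleast_1d(clamped)
        hourly["category"] = classify_stress(utci)
        hourly.to_csv(outdir / f"utci_{year}.csv", index=False)

        daily = station_io.aggregate_daily(
            obs, utci, midday_hour=config.midday_hour,
            min_valid_hours=config.min_valid_hours,
        )
        station_io.write_daily(daily, outdir / f"daily_{year}.csv")
        logger.info("utci: %d -> %d days (%d clamped hours)",
                    year, len(daily), int(np.sum(hourly["clamped"])))


def stage_strain(config: RunConfig) -> None:
    """Heat-balance strain and daily budgets from the cached UTCI files."""
    outdir = Path(config.outdir)
    for year in config.years:
        obs = station_io.read_hourly(outdir / f"hourly_{year}.csv")
        hourly = pd.read_csv(outdir / f"utci_{year}.csv")
        strain = hourly_strain(
            obs, hourly["tmrt"].to_numpy(), config.person, config.strain_constants
        )
        strain.to_csv(outdir / f"strain_{year}.csv", index=False)
        budgets = strain_day_table(strain, hourly["utci"].to_numpy())
        budgets.to_csv(outdir / f"strain_budgets_{year}.csv", index=False)
        logger.info("strain: %d -> %d day budgets", year, len(budgets))


def _daily_categories(config: RunConfig, daily: pd.DataFrame) -> np.ndarray:
    basis = daily[config.day_category_basis]
    valid = basis.notna()
    cats = np.full(len(daily), "NTS", dtype=object)
    if valid.any():
        cats[valid.to_numpy()] = classify_stress(basis[valid].to_numpy(float))
    return cats


def stage_mortality(config: RunConfig) -> None:
    """Synthetic daily deaths per year from the cached daily categories."""
    outdir = Path(config.outdir)
    rows = []
    for year in config.years:
        daily = station_io.read_daily(outdir / f"daily_{year}.csv")
        cats = _daily_categories(config, daily)
        scenario = replace(config.mortality_scenario, seed=config.year_seed(year, 1))
        deaths = generate_mortality(cats, scenario)
        for date, cat, n in zip(daily["date"], cats, deaths):
            rows.append({"city_id": "SYNCITY", "date": date, "year": year,
                         "category": cat, "deaths": int(n),
                         "population": scenario.population})
    pd.DataFrame(rows).to_csv(outdir / "mortality_daily.csv", index=False)
    logger.info("mortality: %d daily records", len(rows))


def stage_pollution(config: RunConfig) -> None:
    outdir = Path(config.outdir)
    frames = []
    for year in config.years:
        scenario = config.scenario if year == config.analysis_year else config.reference_scenario
        frame = generate_pollution(
            scenario.days, seed=config.year_seed(year, 2),
            year=year, month=config.month,
        )
        frame.insert(0, "year", year)
        frames.append(frame)
    pd.concat(frames).to_csv(outdir / "pollution_daily.csv", index=False)


def stage_report(config: RunConfig) -> ReportBundle:
    """Assemble the per-year aggregate table and the final report.

    Reads only cached stage outputs, so re-running this stage alone
    reproduces the final report byte for byte.
    """
    outdir = Path(config.outdir)
    mortality_daily = pd.read_csv(outdir / "mortality_daily.csv")
    pollution_daily = pd.read_csv(outdir / "pollution_daily.csv")

    agg_rows = []
    indicator_rows = []
    for year in config.years:
        daily = station_io.read_daily(outdir / f"daily_{year}.csv")
        budgets = pd.read_csv(outdir / f"strain_budgets_{year}.csv")
        cats = _daily_categories(config, daily)
        shs_days = int((cats == "SHS").sum())
        vshs_days = int(np.isin(cats, ["VSHS", "above scale"]).sum())
        year_mort = mortality_daily[mortality_daily["year"] == year]
        year_poll = pollution_daily[pollution_daily["year"] == year]
        indic = count_threshold_days(daily)
        waves = detect_heat_waves(
            pd.Series(daily["tmax"].to_numpy(float), index=pd.to_datetime(daily["date"]))
        )
        agg_rows.append(
            {
                "year": year,
                "deaths": int(year_mort["deaths"].sum()),
                "population": int(year_mort["population"].iloc[0]),
                "shs_days": shs_days,
                "vshs_days": vshs_days,
                "stress_days": shs_days + vshs_days,
                "utci_mean": float(daily[config.day_category_basis].mean()),
                "tavg_mean": float(daily["tavg"].mean()),
                "o3": float(year_poll["o3"].mean()),
                "pm25": float(year_poll["pm25"].mean()),
                "hst_mean": float(budgets["hst_hours"].mean()),
                "hrt_mean": float(budgets["hrt_hours"].mean()),
            }
        )
        indicator_rows.append(
            {
                "year": year,
                "hot_days": indic.hot_days,
                "very_hot_days": indic.very_hot_days,
                "extremely_hot_days": indic.extremely_hot_days,
                "warm_nights": indic.warm_nights,
                "tropical_nights": indic.tropical_nights,
                "n_heat_waves": len(waves),
                "heat_wave_days": sum(w.length for w in waves),
            }
        )

    aggregates = pd.DataFrame(agg_rows)
    indicators = pd.DataFrame(indicator_rows)

    # anomalies of the analysis year against the reference period
    ref_mask = aggregates["year"].isin(config.reference_years)
    analysis = aggregates[aggregates["year"] == config.analysis_year].iloc[0]
    utci_anom = anomaly(analysis["utci_mean"], aggregates.loc[ref_mask, "utci_mean"])
    tavg_anom = anomaly(analysis["tavg_mean"], aggregates.loc[ref_mask, "tavg_mean"])

    table1 = table1_report(aggregates, config.reference_years)

    aggregates.to_csv(outdir / "aggregates.csv", index=False, float_format="%.6f")
    indicators.to_csv(outdir / "indicators.tsv", sep="\t", index=False)
    table1.to_csv(outdir / "table1.tsv", sep="\t", index=False, na_rep="")

    config_payload = _plain(config.to_dict())
    config_payload.pop("outdir", None)
    metadata = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config_payload,
        "utci_coefficients": {
            "version": UTCI_COEFFICIENT_VERSION,
            "sha256": UTCI_COEFFICIENT_SHA256,
        },
        "thresholds": {
            "s_overheat_wm2": S_OVERHEAT_THRESHOLD,
            "hr_warning_bpm": HR_WARNING_THRESHOLD,
            "hsi_warning_pct": HSI_WARNING_THRESHOLD,
            "hst_utci_c": HST_UTCI_THRESHOLD,
            "hrt_utci_c": HRT_UTCI_THRESHOLD,
            "min_valid_hours": config.min_valid_hours,
        },
        "anomalies": {
            "utci_midday_abs": utci_anom.absolute,
            "utci_midday_sd": utci_anom.relative_sd,
            "tavg_abs": tavg_anom.absolute,
            "tavg_sd": tavg_anom.relative_sd,
        },
    }
    with open(outdir / "metadata.json", "w") as handle:
        json.dump(_plain(metadata), handle, indent=2, sort_keys=True)

    return ReportBundle(
        outdir=outdir, aggregates=aggregates, table1=table1,
        indicators=indicators, metadata=metadata,
    )


def table1_report(aggregates: pd.DataFrame, reference_years) -> pd.DataFrame:
    """Format the per-year report table with reference-relative columns.

    Columns: TMrel, SHRMrel, mean monthly UTCI, strong-heat days, O₃ and
    PM2.5 means plus their relative values; a reference-mean row (relative
    columns exactly 100) is appended.  Years with missing death counts get
    a blank TMrel and are excluded from the reference mean.
    """
    frame = aggregates.copy()
    ref = frame[frame["year"].isin(list(reference_years))]

    tm_ref = reference_mean(ref["deaths"])
    pop_rate = frame["population"] / 100_000.0
    frame["shrm"] = [
        shrm(pr, s, v) for pr, s, v in zip(pop_rate, frame["shs_days"], frame["vshs_days"])
    ]
    shrm_ref = reference_mean(frame.loc[frame["year"].isin(list(reference_years)), "shrm"])
    o3_ref = reference_mean(ref["o3"])
    pm25_ref = reference_mean(ref["pm25"])

    out = pd.DataFrame(
        {
            "period": frame["year"].astype(str),
            "tmrel_pct": [
                tm_rel(d, tm_ref) if pd.notna(d) else np.nan for d in frame["deaths"]
            ],
            "shrmrel_pct": [
                shrm_rel(s, shrm_ref) if shrm_ref > 0 else np.nan for s in frame["shrm"]
            ],
            "utci_mean": frame["utci_mean"],
            "heat_stress_days": frame["stress_days"].astype(float),
            "o3_ugm3": frame["o3"],
            "o3_pct": 100.0 * frame["o3"] / o3_ref,
            "pm25_ugm3": frame["pm25"],
            "pm25_pct": 100.0 * frame["pm25"] / pm25_ref,
        }
    )

    ref_out = out[out["period"].isin([str(y) for y in reference_years])]
    ref_row = {
        "period": _REFERENCE_LABEL,
        "tmrel_pct": 100.0,
        "shrmrel_pct": 100.0 if shrm_ref > 0 else np.nan,
        "utci_mean": ref_out["utci_mean"].mean(),
        "heat_stress_days": ref_out["heat_stress_days"].mean(),
        "o3_ugm3": o3_ref,
        "o3_pct": 100.0,
        "pm25_ugm3": pm25_ref,
        "pm25_pct": 100.0,
    }
    analysis_rows = out[~out["period"].isin([str(y) for y in reference_years])]
    ref_rows = out[out["period"].isin([str(y) for y in reference_years])]
    out = pd.concat(
        [ref_rows, pd.DataFrame([ref_row]), analysis_rows], ignore_index=True
    )
    return out.round(1)


def run_analysis(config: RunConfig) -> ReportBundle:
    """Run every stage end to end and return the assembled report bundle."""
    stage_simulate(config)
    stage_utci(config)
    stage_strain(config)
    stage_mortality(config)
    stage_pollution(config)
    return stage_report(config)
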