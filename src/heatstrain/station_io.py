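"""Station weather, mortality and pollution tables.

This module houses the shared data model of the package and the readers,
writers and daily aggregation that every downstream stage builds on.  The
atom of all computation is one *station-hour* of synoptic observations:

=========  =========================================================
column     meaning
=========  =========================================================
station_id identifier of the synoptic station
timestamp  observation time, stored in UTC (tz-aware)
ta         air temperature, °C
vp         water-vapour pressure, hPa
v10        wind speed at 10 m, m·s⁻¹
cloud      total cloud cover as a fraction in [0, 1]
=========  =========================================================

Cloud cover may arrive in oktas (0–8) and is normalised to a fraction on
read; the dialect is declared in :class:`CsvDialect`, never guessed.
Timestamps without an explicit UTC offset are interpreted as UTC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("heatstrain")

HOURLY_COLUMNS = ["station_id", "timestamp", "ta", "vp", "v10", "cloud"]

#: fixed column order of the daily summary table (documented in the README)
DAILY_COLUMNS = [
    "station_id", "date", "tmax", "tmin", "tavg",
    "utci_avg", "utci_max", "utci_avg_12", "utci_max_12",
    "n_hours", "complete",
]

MORTALITY_COLUMNS = ["city_id", "year", "month", "deaths", "population"]
POLLUTION_COLUMNS = ["station_id", "date", "pm25", "o3"]

#: hours required for a station-day to count as complete (configurable)
DEFAULT_MIN_VALID_HOURS = 18


class StationFileError(ValueError):
    """Structural problem in an input table (missing column, duplicates...)."""


@dataclass(frozen=True)
class CsvDialect:
    """Declared format of a delimited station file.

    Parameters
    ----------
    delimiter
        Field separator.
    cloud_unit
        ``"fraction"`` (values already in [0, 1]) or ``"oktas"`` (0–8,
        divided by 8 on read).
    missing_token
        Explicit sentinel for missing values; never a silent zero.
    """

    delimiter: str = ","
    cloud_unit: str = "fraction"
    missing_token: str = "NA"

    def __post_init__(self) -> None:
        if self.cloud_unit not in ("fraction", "oktas"):
            raise ValueError(f"unknown cloud_unit {self.cloud_unit!r}")


@dataclass(frozen=True)
class HourlyObservation:
    """One station-hour of meteorology; scalar counterpart of the hourly frame."""

    station_id: str
    timestamp: pd.Timestamp
    ta: float
    vp: float
    v10: float
    cloud: float

    def __post_init__(self) -> None:
        problems = _row_problems(self.ta, self.vp, self.v10, self.cloud)
        if problems:
            raise ValueError("; ".join(problems))


def _row_problems(ta: float, vp: float, v10: float, cloud: float) -> list[str]:
    """Invariant violations of a single observation row (empty list if valid)."""
    problems = []
    if not np.isfinite(ta):
        problems.append("ta not finite")
    if not np.isfinite(vp) or vp < 0:
        problems.append("vp must be finite and >= 0")
    if not np.isfinite(v10) or v10 < 0:
        problems.append("v10 must be finite and >= 0")
    if not np.isfinite(cloud) or not 0.0 <= cloud <= 1.0:
        problems.append("cloud must lie in [0, 1]")
    return problems


def read_hourly(path, dialect: CsvDialect = CsvDialect()) -> pd.DataFrame:
    """Read and validate an hourly station file.

    Rows violating the observation invariants are rejected (with per-row
    diagnostics logged and collected in ``df.attrs["rejected_rows"]``);
    structural problems raise :class:`StationFileError`.

    Returns
    -------
    pandas.DataFrame
        Valid observations in ``HOURLY_COLUMNS`` order, sorted by station
        and timestamp, cloud cover as a fraction.
    """
    raw = pd.read_csv(
        path, sep=dialect.delimiter, na_values=[dialect.missing_token],
        keep_default_na=False, dtype={"station_id": str},
    )
    missing = [c for c in HOURLY_COLUMNS if c not in raw.columns]
    if missing:
        raise StationFileError(f"{path}: missing required column(s) {missing}")
    raw = raw[HOURLY_COLUMNS].copy()

    # line numbers refer to the physical file (1-based, header on line 1)
    raw.index = raw.index + 2

    try:
        ts = pd.to_datetime(raw["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        ts = pd.to_datetime(raw["timestamp"], utc=True, errors="coerce")
    raw["timestamp"] = ts

    for col in ("ta", "vp", "v10", "cloud"):
        raw[col] = pd.to_numeric(raw[col], errors="coerce")
    if dialect.cloud_unit == "oktas":
        raw["cloud"] = raw["cloud"] / 8.0

    rejected: list[dict] = []
    keep = np.ones(len(raw), dtype=bool)
    for pos, (line, row) in enumerate(raw.iterrows()):
        if pd.isna(row["timestamp"]):
            rejected.append({"line": int(line), "reason": "unparseable timestamp"})
            keep[pos] = False
            continue
        problems = _row_problems(row["ta"], row["vp"], row["v10"], row["cloud"])
        if problems:
            rejected.append({"line": int(line), "reason": "; ".join(problems)})
            keep[pos] = False
    for item in rejected:
        logger.warning("%s line %d rejected: %s", path, item["line"], item["reason"])

    frame = raw[keep].reset_index(drop=True)
    dup = frame.duplicated(subset=["station_id", "timestamp"], keep=False)
    if dup.any():
        pairs = frame.loc[dup, ["station_id", "timestamp"]].head(3).to_dict("records")
        raise StationFileError(f"{path}: duplicate station-hour record(s), e.g. {pairs}")
    frame = frame.sort_values(["station_id", "timestamp"], kind="stable")
    frame = frame.reset_index(drop=True)
    frame.attrs["rejected_rows"] = rejected
    return frame


def write_hourly(frame: pd.DataFrame, path, dialect: CsvDialect = CsvDialect()) -> None:
    """Write an hourly frame so that ``read_hourly`` round-trips it exactly."""
    out = frame[HOURLY_COLUMNS].copy()
    if dialect.cloud_unit == "oktas":
        out["cloud"] = out["cloud"] * 8.0
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, sep=dialect.delimiter, index=False,
               na_rep=dialect.missing_token)


def validate_hourly(frame: pd.DataFrame) -> None:
    """Raise ``ValueError`` if any row of an in-memory hourly frame is invalid."""
    bad = np.zeros(len(frame), dtype=bool)
    bad |= ~np.isfinite(frame["ta"].to_numpy(float))
    bad |= frame["vp"].to_numpy(float) < 0
    bad |= frame["v10"].to_numpy(float) < 0
    cloud = frame["cloud"].to_numpy(float)
    bad |= (cloud < 0) | (cloud > 1)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} invalid observation row(s)")
    if frame.duplicated(subset=["station_id", "timestamp"]).any():
        raise ValueError("duplicate station-hour records")


def aggregate_daily(
    obs: pd.DataFrame,
    utci: np.ndarray | pd.Series | None = None,
    midday_hour: int = 12,
    min_valid_hours: int = DEFAULT_MIN_VALID_HOURS,
) -> pd.DataFrame:
    """Aggregate hourly observations (and optional matching UTCI values) to days.

    The 24-h statistics (tmax/tmin/tavg, utci_avg/utci_max) use all valid
    hours of the civil UTC date; the ``*_12`` columns use only the record at
    ``midday_hour`` UTC and are left missing (never imputed) on days without
    one.  Days with fewer than ``min_valid_hours`` hours are flagged
    ``complete=False``.

    Parameters
    ----------
    obs
        Hourly frame in ``HOURLY_COLUMNS`` layout.
    utci
        Optional UTCI values aligned row-for-row with ``obs``.
    midday_hour
        Hour of day (UTC) treated as the midday observation; 12 UTC is
        14:00 CEST, the warmest part of a Central European summer day.
    """
    work = obs[["station_id", "timestamp", "ta"]].copy()
    if utci is not None:
        values = np.asarray(utci, dtype=float)
        if values.shape != (len(obs),):
            raise ValueError("utci must align row-for-row with the observations")
        work["utci"] = values
    work["date"] = work["timestamp"].dt.tz_convert("UTC").dt.date
    work["hour"] = work["timestamp"].dt.tz_convert("UTC").dt.hour

    rows = []
    for (station, date), day in work.groupby(["station_id", "date"], sort=True):
        midday = day[day["hour"] == midday_hour]
        row = {
            "station_id": station,
            "date": date,
            "tmax": day["ta"].max(),
            "tmin": day["ta"].min(),
            "tavg": day["ta"].mean(),
            "utci_avg": np.nan,
            "utci_max": np.nan,
            "utci_avg_12": np.nan,
            "utci_max_12": np.nan,
            "n_hours": len(day),
            "complete": len(day) >= min_valid_hours,
        }
        if utci is not None:
            row["utci_avg"] = day["utci"].mean()
            row["utci_max"] = day["utci"].max()
            if len(midday):
                row["utci_avg_12"] = midday["utci"].mean()
                row["utci_max_12"] = midday["utci"].max()
        rows.append(row)
    daily = pd.DataFrame(rows, columns=DAILY_COLUMNS)
    daily.attrs["min_valid_hours"] = min_valid_hours
    daily.attrs["midday_hour"] = midday_hour
    return daily


def write_daily(daily: pd.DataFrame, path) -> None:
    daily[DAILY_COLUMNS].to_csv(path, index=False, na_rep="NA")


def read_daily(path) -> pd.DataFrame:
    frame = pd.read_csv(path, na_values=["NA"], keep_default_na=False,
                        dtype={"station_id": str})
    missing = [c for c in DAILY_COLUMNS if c not in frame.columns]
    if missing:
        raise StationFileError(f"{path}: missing required column(s) {missing}")
    frame["date"] = pd.to_datetime(frame["date"]).dt.date
    return frame[DAILY_COLUMNS]


def read_mortality(path) -> pd.DataFrame:
    """Monthly all-cause death counts and populations per city.

    Expected columns: ``city_id, year, month, deaths, population``.  Missing
    death counts stay missing; they are excluded from reference means later,
    never imputed.
    """
    frame = pd.read_csv(path, na_values=["NA", ""], keep_default_na=False,
                        dtype={"city_id": str})
    missing = [c for c in MORTALITY_COLUMNS if c not in frame.columns]
    if missing:
        raise StationFileError(f"{path}: missing required column(s) {missing}")
    if (frame["deaths"].dropna() < 0).any() or (frame["population"] <= 0).any():
        raise StationFileError(f"{path}: deaths must be >= 0 and population > 0")
    return frame[MORTALITY_COLUMNS]


def read_pollution(path) -> pd.DataFrame:
    """Daily PM2.5 / O₃ concentrations (µg·m⁻³) per monitoring station."""
    frame = pd.read_csv(path, na_values=["NA", ""], keep_default_na=False,
                        dtype={"station_id": str})
    missing = [c for c in POLLUTION_COLUMNS if c not in frame.columns]
    if missing:
        raise StationFileError(f"{path}: missing required column(s) {missing}")
    for col in ("pm25", "o3"):
        if (frame[col].dropna() < 0).any():
            raise StationFileError(f"{path}: negative {col} concentration")
    frame["date"] = pd.to_datetime(frame["date"]).dt.date
    return frame[POLLUTION_COLUMNS]
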