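"""Climatological heat indicators: threshold days, heat waves, anomalies.

Indicator definitions (all strict inequalities, boundary values excluded):

* hot / very hot / extremely hot day: tmax > 25 / 30 / 35 °C
* warm / tropical night: tmin > 18 / 20 °C
* heat wave: a maximal run of at least 3 consecutive days with
  tmax > 30 °C; two runs separated by a single sub-threshold day are
  reported as two distinct waves.

Anomalies of a monthly statistic against a multiannual reference are
expressed both in the variable's own units and in multiples of the
reference standard deviation (sample SD, n−1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta

import numpy as np
import pandas as pd

HOT_DAY_THRESHOLD = 25.0
VERY_HOT_DAY_THRESHOLD = 30.0
EXTREMELY_HOT_DAY_THRESHOLD = 35.0
WARM_NIGHT_THRESHOLD = 18.0
TROPICAL_NIGHT_THRESHOLD = 20.0
HEAT_WAVE_THRESHOLD = 30.0
HEAT_WAVE_MIN_LENGTH = 3


@dataclass(frozen=True)
class HeatWave:
    """One maximal run of consecutive days above the wave threshold."""

    start: object  # date label of the first day
    length: int


@dataclass
class HeatIndicators:
    """Threshold-day counts and detected heat waves for one station-month."""

    hot_days: int = 0
    very_hot_days: int = 0
    extremely_hot_days: int = 0
    warm_nights: int = 0
    tropical_nights: int = 0
    heat_waves: list[HeatWave] = field(default_factory=list)
    n_days: int = 0
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not (self.extremely_hot_days <= self.very_hot_days <= self.hot_days):
            raise ValueError("threshold-day counts must nest")
        if self.tropical_nights > self.warm_nights:
            raise ValueError("tropical nights cannot exceed warm nights")


@dataclass(frozen=True)
class AnomalyResult:
    """Deviation of a value from a multiannual reference.

    ``relative_sd`` is the absolute anomaly divided by the reference SD and
    is NaN when the reference is constant (zero SD).
    """

    absolute: float
    relative_sd: float
    ref_mean: float
    ref_sd: float
    ref_n: int


def count_threshold_days(daily: pd.DataFrame) -> HeatIndicators:
    """Count hot/very hot/extremely hot days and warm/tropical nights.

    ``daily`` is a daily-summary frame; days flagged incomplete are
    excluded from the counts and reported in ``n_excluded``.
    """
    if len(daily) == 0:
        return HeatIndicators()
    if daily["date"].duplicated().any():
        raise ValueError("multiple records for one date")
    if "complete" in daily.columns:
        usable = daily[daily["complete"].astype(bool)]
    else:
        usable = daily
    tmax = usable["tmax"].to_numpy(float)
    tmin = usable["tmin"].to_numpy(float)
    return HeatIndicators(
        hot_days=int((tmax > HOT_DAY_THRESHOLD).sum()),
        very_hot_days=int((tmax > VERY_HOT_DAY_THRESHOLD).sum()),
        extremely_hot_days=int((tmax > EXTREMELY_HOT_DAY_THRESHOLD).sum()),
        warm_nights=int((tmin > WARM_NIGHT_THRESHOLD).sum()),
        tropical_nights=int((tmin > TROPICAL_NIGHT_THRESHOLD).sum()),
        n_days=int(len(usable)),
        n_excluded=int(len(daily) - len(usable)),
    )


def detect_heat_waves(
    tmax,
    threshold: float = HEAT_WAVE_THRESHOLD,
    min_length: int = HEAT_WAVE_MIN_LENGTH,
) -> list[HeatWave]:
    """Find maximal runs of consecutive days with tmax strictly above threshold.

    ``tmax`` may be a plain sequence (assumed contiguous daily values) or a
    pandas Series indexed by date, in which case a gap in the dates raises
    ``ValueError`` — the caller must fill or split the series first.
    Returned waves are non-overlapping and ordered by start; the ``start``
    label is the series index (or 0-based position for plain sequences).
    """
    if isinstance(tmax, pd.Series):
        index = list(tmax.index)
        if len(index) > 1:
            idx = pd.Index(index)
            if isinstance(idx, pd.DatetimeIndex) or hasattr(index[0], "toordinal"):
                deltas = np.diff([pd.Timestamp(d).toordinal() for d in index])
                if np.any(deltas != 1):
                    raise ValueError("gap in dates: fill or split the series first")
        values = tmax.to_numpy(float)
    else:
        values = np.asarray(tmax, dtype=float)
        index = list(range(len(values)))

    waves: list[HeatWave] = []
    run_start = None
    for pos, value in enumerate(values):
        if value > threshold:
            if run_start is None:
                run_start = pos
        else:
            if run_start is not None and pos - run_start >= min_length:
                waves.append(HeatWave(start=index[run_start], length=pos - run_start))
            run_start = None
    if run_start is not None and len(values) - run_start >= min_length:
        waves.append(HeatWave(start=index[run_start], length=len(values) - run_start))
    return waves


def anomaly(value: float, reference) -> AnomalyResult:
    """Anomaly of ``value`` against a reference series of the same statistic.

    absolute = value − mean(reference); relative = absolute / sd(reference)
    with the sample (n−1) standard deviation.  A constant reference yields
    a defined absolute anomaly but an undefined (NaN) relative one.
    """
    ref = np.asarray(pd.Series(reference).dropna(), dtype=float)
    if len(ref) < 2:
        raise ValueError("reference must contain at least 2 values")
    ref_mean = float(ref.mean())
    ref_sd = float(ref.std(ddof=1))
    absolute = float(value) - ref_mean
    relative = absolute / ref_sd if ref_sd > 0 else float("nan")
    return AnomalyResult(
        absolute=absolute, relative_sd=relative,
        ref_mean=ref_mean, ref_sd=ref_sd, ref_n=len(ref),
    )


def monthly_mean(series) -> tuple[float, int]:
    """Arithmetic mean over valid (non-missing) records, with their count."""
    values = pd.Series(series).dropna().to_numpy(float)
    if len(values) == 0:
        raise ValueError("no valid records to average")
    return float(values.mean()), int(len(values))
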