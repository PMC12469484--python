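"""Day-of-year percentile climatology and heatwave detection.

A heatwave threshold is the day-of-year 90th percentile of the chosen
thermal index (TMAX or HI), computed over a 30-year reference period
(default 1991-2020) and smoothed by pooling each day with a centered
7-day window that wraps across year boundaries.  A heatwave event is a
maximal run of at least ``min_duration`` (default 3) consecutive days on
which the index strictly exceeds its day-of-year threshold.

Calendar conventions
--------------------
All non-leap dates map to a 1..365 day-of-year axis.  Feb 29 is assigned
the fractional position 59.5 (between Feb 28 = 59 and Mar 1 = 60): its
values participate in the pooled windows of neighbouring days, and its
own threshold is interpolated as the mean of the Feb 28 and Mar 1
thresholds.  This keeps pool sizes balanced across the year.

The empirical percentile uses linear interpolation between order
statistics (numpy's ``linear`` convention), recorded in the climatology
metadata for reproducibility.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DayOfYearClimatology",
    "build_climatology",
    "exceedance_series",
    "detect_heatwaves",
    "DetectedRun",
]

QUANTILE_METHOD = "linear"


class InsufficientClimatologyError(ValueError):
    """Reference series too short to build a stable climatology."""


@dataclass
class DayOfYearClimatology:
    """Per day-of-year threshold for one thermal index.

    ``thresholds`` maps day-of-year 1..365 (index 0..364 of the array) to
    the threshold in °C; ``feb29_threshold`` is the interpolated leap-day
    value.
    """

    index_kind: str
    thresholds: np.ndarray
    reference_start: int
    reference_end: int
    percentile: float = 0.90
    window_days: int = 7
    quantile_method: str = QUANTILE_METHOD
    feb29_threshold: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.shape != (365,):
            raise ValueError("thresholds must have one value per day-of-year 1..365")
        if not np.all(np.isfinite(self.thresholds)):
            raise ValueError("every day-of-year must have a finite threshold")
        if self.window_days % 2 != 1:
            raise ValueError("window_days must be odd")
        if np.isnan(self.feb29_threshold):
            self.feb29_threshold = 0.5 * (self.thresholds[58] + self.thresholds[59])

    def threshold_for(self, dates: pd.Series) -> np.ndarray:
        """Threshold for each date in a datetime series."""
        doy = _doy365(pd.to_datetime(dates))
        out = np.empty(len(doy))
        leap = doy == 59.5
        out[leap] = self.feb29_threshold
        idx = doy[~leap].astype(int) - 1
        out[~leap] = self.thresholds[idx]
        return out

    def to_csv(self, path) -> None:
        """Persist as CSV with a ``#``-prefixed metadata header block."""
        buf = io.StringIO()
        buf.write(f"# index_kind: {self.index_kind}\n")
        buf.write(f"# reference_start: {self.reference_start}\n")
        buf.write(f"# reference_end: {self.reference_end}\n")
        buf.write(f"# percentile: {self.percentile}\n")
        buf.write(f"# window_days: {self.window_days}\n")
        buf.write(f"# quantile_method: {self.quantile_method}\n")
        buf.write(f"# feb29_threshold: {float(self.feb29_threshold)!r}\n")
        pd.DataFrame(
            {"doy": np.arange(1, 366), "threshold_c": self.thresholds}
        ).to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "DayOfYearClimatology":
        meta: dict[str, str] = {}
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                else:
                    lines.append(line)
        frame = pd.read_csv(io.StringIO("".join(lines)))
        return cls(
            index_kind=meta["index_kind"],
            thresholds=frame["threshold_c"].to_numpy(),
            reference_start=int(meta["reference_start"]),
            reference_end=int(meta["reference_end"]),
            percentile=float(meta["percentile"]),
            window_days=int(meta["window_days"]),
            quantile_method=meta["quantile_method"],
            feb29_threshold=float(meta["feb29_threshold"]),
        )


def _doy365(dates: pd.DatetimeIndex | pd.Series) -> np.ndarray:
    """Map dates to the 1..365 axis; Feb 29 -> 59.5."""
    dates = pd.DatetimeIndex(dates)
    doy = dates.dayofyear.to_numpy().astype(float)
    leap_year = dates.is_leap_year
    feb29 = leap_year & (doy == 60)
    after = leap_year & (doy > 60)
    doy[after] -= 1.0
    doy[feb29] = 59.5
    return doy


def build_climatology(
    reference: pd.DataFrame,
    index_kind: str = "TMAX",
    value_column: str | None = None,
    percentile: float = 0.90,
    window_days: int = 7,
) -> DayOfYearClimatology:
    """Pooled-window day-of-year percentile thresholds.

    The threshold for day-of-year ``d`` is the empirical ``percentile``
    quantile of all reference values whose day-of-year lies within the
    centered window of ``window_days`` around ``d`` (wrapping across the
    year boundary), pooled over all reference years.

    Parameters
    ----------
    reference
        DataFrame with a ``date`` column and the index values (column
        ``tmax_c`` for TMAX, ``hi_c`` for HI, or ``value_column``).
    """
    if window_days < 1 or window_days % 2 != 1:
        raise ValueError("window_days must be an odd integer >= 1")
    if value_column is None:
        value_column = {"TMAX": "tmax_c", "HI": "hi_c"}.get(index_kind, index_kind)
    dates = pd.to_datetime(reference["date"])
    values = reference[value_column].to_numpy(dtype=float)
    ok = np.isfinite(values)
    dates, values = dates[ok], values[ok]
    years = dates.dt.year
    span_days = (dates.max() - dates.min()).days if len(dates) else 0
    if span_days < 2 * 365 - 1:
        raise InsufficientClimatologyError(
            "reference series must span at least 2 full years"
        )

    doy = _doy365(dates)
    half = window_days // 2
    thresholds = np.empty(365)
    for d in range(1, 366):
        # circular distance on the 365-day axis; Feb 29 sits at 59.5
        dist = np.abs(doy - d)
        dist = np.minimum(dist, 365.0 - dist)
        pool = values[dist <= half]
        thresholds[d - 1] = np.quantile(pool, percentile, method=QUANTILE_METHOD)

    return DayOfYearClimatology(
        index_kind=index_kind,
        thresholds=thresholds,
        reference_start=int(years.min()),
        reference_end=int(years.max()),
        percentile=percentile,
        window_days=window_days,
    )


def exceedance_series(
    index_series: pd.DataFrame,
    climatology: DayOfYearClimatology,
    value_column: str | None = None,
) -> pd.DataFrame:
    """Per-day exceedance table: value, threshold, excess, exceeds flag.

    ``exceeds`` is strict (``value > threshold``); days exactly on the
    threshold do not count.  Missing values yield ``exceeds = False``
    with NaN excess.
    """
    if value_column is None:
        value_column = {"TMAX": "tmax_c", "HI": "hi_c"}.get(
            climatology.index_kind, climatology.index_kind
        )
    dates = pd.to_datetime(index_series["date"])
    values = index_series[value_column].to_numpy(dtype=float)
    thresholds = climatology.threshold_for(dates)
    excess = values - thresholds
    exceeds = np.where(np.isfinite(values), values > thresholds, False)
    return pd.DataFrame(
        {
            "date": dates,
            "index_value": values,
            "threshold": thresholds,
            "excess": excess,
            "exceeds": exceeds.astype(bool),
        }
    )


@dataclass(frozen=True)
class DetectedRun:
    """A maximal exceedance run of sufficient duration (pre-characterization)."""

    start_date: pd.Timestamp
    end_date: pd.Timestamp
    dates: tuple
    excesses: tuple


def detect_heatwaves(
    index_series: pd.DataFrame,
    climatology: DayOfYearClimatology,
    min_duration: int = 3,
    value_column: str | None = None,
) -> list[DetectedRun]:
    """Maximal runs of >= ``min_duration`` consecutive strict-exceedance days.

    A calendar gap in the series or a missing index value breaks a run
    (consecutive means consecutive calendar days with data).  Returned
    runs are ordered by start date and non-overlapping.
    """
    exc = exceedance_series(index_series, climatology, value_column=value_column)
    runs: list[DetectedRun] = []
    cur_dates: list[pd.Timestamp] = []
    cur_excess: list[float] = []
    prev_date = None

    def flush() -> None:
        if len(cur_dates) >= min_duration:
            runs.append(
                DetectedRun(
                    start_date=cur_dates[0],
                    end_date=cur_dates[-1],
                    dates=tuple(cur_dates),
                    excesses=tuple(cur_excess),
                )
            )

    for date, excess, exceeds in zip(exc["date"], exc["excess"], exc["exceeds"]):
        contiguous = prev_date is not None and (date - prev_date).days == 1
        if exceeds and np.isfinite(excess):
            if not contiguous and cur_dates:
                flush()
                cur_dates, cur_excess = [], []
            cur_dates.append(date)
            cur_excess.append(float(excess))
        else:
            if cur_dates:
                flush()
                cur_dates, cur_excess = [], []
        prev_date = date
    if cur_dates:
        flush()
    return runs
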