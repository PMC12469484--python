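"""Heatwave event statistics and the daily cumulative-intensity exposure.

Each detected event (a run of >= 3 consecutive strict-exceedance days)
is summarised by the standard excess-based statistics:

====== =========================================================
D      duration in days
Imean  mean daily excess above threshold (°C)
Imax   maximum daily excess (°C); the peak
Ivar   population variance of the daily excesses (°C²)
Icum   summed excess over the event (°C); Icum = D * Imean exactly
RO     onset rate: Imax / #event-days strictly before the peak (°C/day)
RD     decline rate: Imax / #event-days strictly after the peak (°C/day)
====== =========================================================

RO/RD denominators are floored at 1 so that an event peaking on its
first (last) day has RO (RD) equal to Imax.  Peak ties break to the
earliest day.  All intensities are excesses over the day-of-year
threshold, not absolute temperatures.

``daily_icum`` converts the event list into a daily exposure series
(within-event running cumulative excess, zero outside events), the form
needed for the lag-0..7 distributed-lag design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climatology import DetectedRun

__all__ = ["HeatwaveEvent", "characterize", "characterize_runs", "daily_icum", "events_to_frame"]


class InconsistentEventError(ValueError):
    """Event vector violates the event definition (non-positive excess)."""


@dataclass(frozen=True)
class HeatwaveEvent:
    index_kind: str
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    peak_date: pd.Timestamp
    duration: int
    imean: float
    imax: float
    ivar: float
    icum: float
    onset_rate: float
    decline_rate: float
    excesses: tuple


def characterize(
    excesses,
    dates,
    index_kind: str = "TMAX",
    min_duration: int = 3,
) -> HeatwaveEvent:
    """Event statistics from the per-day excess vector.

    ``Ivar`` is the population (1/D) variance: the statistic describes
    the realised event, not a sample estimate.
    """
    excesses = np.asarray(excesses, dtype=float)
    dates = pd.to_datetime(pd.Series(list(dates)))
    if len(excesses) != len(dates):
        raise ValueError("excesses and dates must have equal length")
    if len(excesses) < min_duration:
        raise InconsistentEventError(
            f"event must span >= {min_duration} days, got {len(excesses)}"
        )
    if np.any(excesses <= 0) or not np.all(np.isfinite(excesses)):
        raise InconsistentEventError("all in-event excesses must be finite and > 0")

    d = len(excesses)
    imean = float(excesses.mean())
    peak_idx = int(np.argmax(excesses))  # argmax -> earliest on ties
    imax = float(excesses[peak_idx])
    ivar = float(excesses.var())  # population variance
    icum = float(d * imean)  # the identity Icum = D * Imean holds exactly
    onset = imax / max(1, peak_idx)
    decline = imax / max(1, d - 1 - peak_idx)
    return HeatwaveEvent(
        index_kind=index_kind,
        start_date=dates.iloc[0],
        end_date=dates.iloc[-1],
        peak_date=dates.iloc[peak_idx],
        duration=d,
        imean=imean,
        imax=imax,
        ivar=ivar,
        icum=icum,
        onset_rate=onset,
        decline_rate=decline,
        excesses=tuple(float(x) for x in excesses),
    )


def characterize_runs(
    runs: list[DetectedRun], index_kind: str = "TMAX"
) -> list[HeatwaveEvent]:
    return [characterize(r.excesses, r.dates, index_kind=index_kind) for r in runs]


def daily_icum(series_dates, events: list[HeatwaveEvent]) -> pd.DataFrame:
    """Daily exposure: within-event running cumulative excess.

    On day ``t`` inside an event, the value is the sum of that event's
    excesses from its start through ``t`` (so the last event day equals
    the event's Icum); zero elsewhere.  Events must be disjoint.
    """
    dates = pd.DatetimeIndex(pd.to_datetime(pd.Series(list(series_dates))))
    icum = np.zeros(len(dates))
    in_event = np.zeros(len(dates), dtype=bool)
    pos = {d: i for i, d in enumerate(dates)}

    claimed: set = set()
    for ev in sorted(events, key=lambda e: e.start_date):
        running = 0.0
        for offset, excess in enumerate(ev.excesses):
            day = ev.start_date + pd.Timedelta(days=offset)
            if day in claimed:
                raise ValueError(f"overlapping events at {day.date()}")
            claimed.add(day)
            running += excess
            i = pos.get(day)
            if i is not None:
                icum[i] = running
                in_event[i] = True
    return pd.DataFrame({"date": dates, "icum_daily": icum, "in_event": in_event})


def events_to_frame(events: list[HeatwaveEvent]) -> pd.DataFrame:
    """Events table (one row per event) for CSV export."""
    return pd.DataFrame(
        [
            {
                "index_kind": e.index_kind,
                "start": e.start_date.date().isoformat(),
                "end": e.end_date.date().isoformat(),
                "peak": e.peak_date.date().isoformat(),
                "d": e.duration,
                "imean": e.imean,
                "imax": e.imax,
                "ivar": e.ivar,
                "icum": e.icum,
                "ro": e.onset_rate,
                "rd": e.decline_rate,
            }
            for e in events
        ],
        columns=[
            "index_kind", "start", "end", "peak", "d", "imean",
            "imax", "ivar", "icum", "ro", "rd",
        ],
    )
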