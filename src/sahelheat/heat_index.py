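"""Rothfusz heat-index computation.

The heat index (HI) estimates perceived temperature from air temperature
and relative humidity via the Rothfusz regression of Steadman's
apparent-temperature model, as operationalised by the US National Weather
Service.  The regression is a Fahrenheit polynomial, so all internal
computation is done in °F; the public interface takes and returns °C.

The scheme is piecewise:

* ``T < 80 °F``: a simplified linear formula
  ``HI = 0.5 * (T + 61 + (T - 68) * 1.2 + R * 0.094)``.
  If that result exceeds 80 °F, the full regression is evaluated instead.
* ``T >= 80 °F``: the full nine-term regression.
* Dry adjustment, **subtracted**, when ``R < 13 %`` and ``80 <= T <= 120 °F``:
  ``((13 - R) / 4) * sqrt((17 - |T - 95|) / 17)``.
* Humid adjustment, **added**, when ``R > 85 %`` and ``80 <= T <= 87 °F``:
  ``((R - 85) / 10) * ((87 - T) / 5)``.

Daily maximum temperature (TMAX) is paired with same-day minimum relative
humidity (RHMIN), approximating conditions at the daily thermal peak.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Branch",
    "TempHumidPair",
    "HeatIndexValue",
    "celsius_to_fahrenheit",
    "fahrenheit_to_celsius",
    "compute_heat_index",
    "compute_hi_series",
]


class Branch(str, enum.Enum):
    """Which region of the piecewise scheme produced the value."""

    SIMPLE = "simple"
    FULL = "full"
    FULL_DRY_ADJUSTED = "full_dry_adjusted"
    FULL_HUMID_ADJUSTED = "full_humid_adjusted"


@dataclass(frozen=True)
class TempHumidPair:
    """A (temperature, relative humidity) pair; °C at the interface."""

    t_c: float
    rh_pct: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.t_c):
            raise ValueError(f"temperature must be finite, got {self.t_c!r}")
        if not (0.0 <= self.rh_pct <= 100.0):
            raise ValueError(
                f"relative humidity must be in [0, 100] %, got {self.rh_pct!r}"
            )


@dataclass(frozen=True)
class HeatIndexValue:
    hi_c: float
    branch: Branch


def celsius_to_fahrenheit(t_c):
    """°C -> °F.  Raises on non-finite scalar input."""
    arr = np.asarray(t_c, dtype=float)
    if arr.ndim == 0 and not np.isfinite(arr):
        raise ValueError(f"temperature must be finite, got {t_c!r}")
    out = arr * 9.0 / 5.0 + 32.0
    return float(out) if np.ndim(t_c) == 0 else out


def fahrenheit_to_celsius(t_f):
    """°F -> °C, the exact inverse of :func:`celsius_to_fahrenheit`."""
    arr = np.asarray(t_f, dtype=float)
    if arr.ndim == 0 and not np.isfinite(arr):
        raise ValueError(f"temperature must be finite, got {t_f!r}")
    out = (arr - 32.0) * 5.0 / 9.0
    return float(out) if np.ndim(t_f) == 0 else out


# Rothfusz regression coefficients (°F).
_C = (
    -42.379,
    2.04901523,
    10.14333127,
    -0.22475541,
    -0.00683783,
    -0.05481717,
    0.00122874,
    0.00085282,
    -0.00000199,
)


def _rothfusz_f(t_f, r):
    """Full nine-term regression, °F in / °F out.  Vectorised."""
    return (
        _C[0]
        + _C[1] * t_f
        + _C[2] * r
        + _C[3] * t_f * r
        + _C[4] * t_f * t_f
        + _C[5] * r * r
        + _C[6] * t_f * t_f * r
        + _C[7] * t_f * r * r
        + _C[8] * t_f * t_f * r * r
    )


def _simple_f(t_f, r):
    """Simplified low-temperature formula, °F in / °F out."""
    return 0.5 * (t_f + 61.0 + (t_f - 68.0) * 1.2 + r * 0.094)


def _dry_adjustment_f(t_f, r):
    # the radicand crosses zero at T = 112 °F; the adjustment vanishes
    # there smoothly, so it is held at zero through the rest of the
    # stated 80-120 °F region
    return ((13.0 - r) / 4.0) * np.sqrt(
        np.maximum(0.0, 17.0 - np.abs(t_f - 95.0)) / 17.0
    )


def _humid_adjustment_f(t_f, r):
    return ((r - 85.0) / 10.0) * ((87.0 - t_f) / 5.0)


def _heat_index_f(t_f: float, r: float) -> tuple[float, Branch]:
    """Scalar piecewise heat index; all quantities in °F."""
    if t_f < 80.0:
        simple = _simple_f(t_f, r)
        if simple <= 80.0:
            return float(simple), Branch.SIMPLE
    hi = float(_rothfusz_f(t_f, r))
    if r < 13.0 and 80.0 <= t_f <= 120.0:
        return hi - float(_dry_adjustment_f(t_f, r)), Branch.FULL_DRY_ADJUSTED
    if r > 85.0 and 80.0 <= t_f <= 87.0:
        return hi + float(_humid_adjustment_f(t_f, r)), Branch.FULL_HUMID_ADJUSTED
    return hi, Branch.FULL


def compute_heat_index(pair: TempHumidPair) -> HeatIndexValue:
    """Heat index for one (TMAX, RHMIN) pair; °C in, °C out."""
    t_f = celsius_to_fahrenheit(pair.t_c)
    hi_f, branch = _heat_index_f(t_f, pair.rh_pct)
    return HeatIndexValue(hi_c=fahrenheit_to_celsius(hi_f), branch=branch)


def compute_hi_series(climate: pd.DataFrame) -> pd.DataFrame:
    """Daily heat-index series from a climate table.

    Parameters
    ----------
    climate
        DataFrame with columns ``date`` (strictly increasing), ``tmax_c``
        and ``rhmin_pct``.  Missing TMAX or RHMIN yields a missing HI for
        that day (flagged via NaN; downstream gap policy decides drop vs.
        interpolate).

    Returns
    -------
    DataFrame with columns ``date``, ``hi_c``, ``branch``.
    """
    required = {"date", "tmax_c", "rhmin_pct"}
    missing_cols = required - set(climate.columns)
    if missing_cols:
        raise ValueError(f"climate table missing columns: {sorted(missing_cols)}")
    dates = pd.to_datetime(climate["date"])
    if len(dates) > 1 and not dates.is_monotonic_increasing:
        raise ValueError("climate dates must be strictly increasing")
    if dates.duplicated().any():
        raise ValueError("climate dates must be strictly increasing (duplicates found)")

    rh = climate["rhmin_pct"].to_numpy(dtype=float)
    valid_rh = rh[np.isfinite(rh)]
    if valid_rh.size and (valid_rh.min() < 0.0 or valid_rh.max() > 100.0):
        raise ValueError("relative humidity outside [0, 100] %")

    tmax = climate["tmax_c"].to_numpy(dtype=float)
    hi = np.full(len(climate), np.nan)
    branch = np.array([""] * len(climate), dtype=object)
    ok = np.isfinite(tmax) & np.isfinite(rh)
    for i in np.flatnonzero(ok):
        hi_f, b = _heat_index_f(celsius_to_fahrenheit(tmax[i]), rh[i])
        hi[i] = fahrenheit_to_celsius(hi_f)
        branch[i] = b.value
    return pd.DataFrame({"date": dates, "hi_c": hi, "branch": branch})
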