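"""Delimited-text readers/writers for the pipeline's artifacts.

Climate tables are CSV with header ``date,tmax_c,rhmin_pct`` (ISO-8601
dates, decimal point, empty cells for missing).  Admissions tables are
CSV with ``date,admissions`` plus the demographic count columns.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

CLIMATE_COLUMNS = ["date", "tmax_c", "rhmin_pct"]


def read_climate_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, parse_dates=["date"])
    missing = set(CLIMATE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"climate CSV missing columns: {sorted(missing)}")
    return frame[CLIMATE_COLUMNS + [c for c in frame.columns if c not in CLIMATE_COLUMNS]]


def write_climate_csv(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    out.to_csv(path, index=False)


def read_admissions_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, parse_dates=["date"])
    if "admissions" not in frame.columns:
        raise ValueError("admissions CSV must have an 'admissions' column")
    return frame


def write_admissions_csv(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    out.to_csv(path, index=False)


def _jsonable(obj):
    """Recursively convert pandas/numpy values for json.dump."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return {"_frame": obj.reset_index().to_dict(orient="list")}
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Timestamp):
        return obj.isoformat()
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)
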