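"""End-to-end orchestration: heat index -> climatology -> detection ->
characterization -> features -> LASSO -> models -> bootstrap -> importance.

A :class:`PipelineConfig` (YAML-serialisable) drives the run.  Every
stochastic stage derives its seed deterministically from the master
seed, and each artifact embeds the config hash and the seeds used, so a
re-run with the same config is byte-identical.

TMAX and HI analyses are independent sub-pipelines sharing the climate
input.  An index with fewer than three detected events is reported as
an ``insufficient_events`` outcome (with whatever was detected), not an
error: a sparse event record that cannot support modelling is a
finding, not a failure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as shio
from .climatology import build_climatology, detect_heatwaves
from .events import characterize_runs, daily_icum, events_to_frame
from .features import (
    DEMOGRAPHIC_COLUMNS,
    build_feature_table,
    lasso_select,
)
from .heat_index import compute_hi_series
from .models import GAMSpec, RFSpec, SplitPlan, XGBSpec, evaluate_models

logger = logging.getLogger("sahelheat")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, tag: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return int(
        np.random.default_rng([int(master_seed), zlib.crc32(tag.encode())]).integers(
            2**31 - 1
        )
    )


@dataclass
class PipelineConfig:
    climate_path: str = "climate.csv"
    reference_path: str | None = None   # defaults to climate_path
    admissions_path: str = "admissions.csv"
    output_dir: str = "output"
    indices: tuple = ("TMAX",)          # any of TMAX, HI
    reference_start: int = 1991
    reference_end: int = 2020
    percentile: float = 0.90
    window_days: int = 7
    min_duration: int = 3
    max_lag: int = 7
    lasso_cv_folds: int = 10
    cv_folds: int = 10
    n_boot: int = 1000
    rf_trees: int = 5000
    xgb_trees: int = 100
    gam_basis_df: int = 50
    shap_max_rows: int = 150
    gap_policy: str = "drop"            # drop | interpolate (missing HI inputs)
    master_seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "indices" in raw:
            raw["indices"] = tuple(raw["indices"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _apply_gap_policy(frame: pd.DataFrame, column: str, policy: str) -> pd.DataFrame:
    if policy == "interpolate":
        out = frame.copy()
        out[column] = out[column].interpolate(limit_area="inside")
        return out
    if policy == "drop":
        return frame  # missing days simply break detection runs
    raise ValueError(f"unknown gap policy: {policy!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict and writes all
    intermediate artifacts under ``config.output_dir``."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "stage_seeds": {},
    }
    report: dict = {"meta": meta, "indices": {}}

    t0 = time.time()
    climate = shio.read_climate_csv(config.climate_path)
    reference = (
        shio.read_climate_csv(config.reference_path)
        if config.reference_path
        else climate
    )
    admissions = shio.read_admissions_csv(config.admissions_path)
    logger.info("load stage done in %.2fs", time.time() - t0)

    ref_years = pd.to_datetime(reference["date"]).dt.year
    ref_mask = (ref_years >= config.reference_start) & (ref_years <= config.reference_end)
    reference = reference.loc[ref_mask].reset_index(drop=True)

    for index_kind in config.indices:
        t0 = time.time()
        entry: dict = {}
        if index_kind == "HI":
            hi = compute_hi_series(climate)
            hi = _apply_gap_policy(hi, "hi_c", config.gap_policy)
            hi_ref = compute_hi_series(reference)
            hi_ref = _apply_gap_policy(hi_ref, "hi_c", config.gap_policy)
            out = hi.copy()
            out["date"] = pd.to_datetime(out["date"]).dt.date
            out.to_csv(out_dir / "hi_series.csv", index=False)
            index_series, index_reference = hi, hi_ref
        else:
            index_series, index_reference = climate, reference

        climatology = build_climatology(
            index_reference,
            index_kind=index_kind,
            percentile=config.percentile,
            window_days=config.window_days,
        )
        climatology.to_csv(out_dir / f"climatology_{index_kind.lower()}.csv")

        runs = detect_heatwaves(
            index_series, climatology, min_duration=config.min_duration
        )
        events = characterize_runs(runs, index_kind=index_kind)
        events_to_frame(events).to_csv(
            out_dir / f"events_{index_kind.lower()}.csv", index=False
        )
        entry["n_events"] = len(events)
        logger.info(
            "[%s] detection done in %.2fs: %d events",
            index_kind, time.time() - t0, len(events),
        )

        if len(events) < 3:
            logger.warning(
                "[%s] insufficient events (%d < 3); skipping modelling — "
                "reported as an outcome, not an error",
                index_kind, len(events),
            )
            entry["status"] = "insufficient_events"
            report["indices"][index_kind] = entry
            continue

        exposure = daily_icum(index_series["date"], events)
        table = build_feature_table(exposure, admissions, max_lag=config.max_lag)
        table["day_index"] = np.arange(len(table), dtype=float)
        table.to_csv(out_dir / f"features_{index_kind.lower()}.csv", index=False)

        lasso_seed = stage_seed(config.master_seed, f"lasso:{index_kind}")
        meta["stage_seeds"][f"lasso:{index_kind}"] = lasso_seed
        predictors = [
            c for c in table.columns if c not in ("date", "admissions", "day_index")
        ]
        sel = lasso_select(
            table[predictors],
            table["admissions"],
            cv_folds=config.lasso_cv_folds,
            seed=lasso_seed,
        )
        shio.write_json(
            {"config_hash": meta["config_hash"], **sel.to_json_dict()},
            out_dir / f"lasso_{index_kind.lower()}.json",
        )
        entry["lasso_selected"] = sel.selected_predictors
        entry["final_feature_set"] = sel.final_feature_set

        model_seed = stage_seed(config.master_seed, f"models:{index_kind}")
        meta["stage_seeds"][f"models:{index_kind}"] = model_seed
        feature_columns = sel.final_feature_set + [
            c for c in DEMOGRAPHIC_COLUMNS if c in table.columns
        ]
        t0 = time.time()
        entry["evaluation"] = evaluate_models(
            table,
            feature_columns=feature_columns,
            specs=[
                GAMSpec(time_basis_df=config.gam_basis_df),
                RFSpec(n_trees=config.rf_trees),
                XGBSpec(n_trees=config.xgb_trees),
            ],
            plan=SplitPlan(cv_folds=config.cv_folds, seed=model_seed),
            n_boot=config.n_boot,
            shap_max_rows=config.shap_max_rows,
        )
        logger.info("[%s] modelling done in %.2fs", index_kind, time.time() - t0)
        report["indices"][index_kind] = entry

    shio.write_json(report, out_dir / "report.json")
    return report
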