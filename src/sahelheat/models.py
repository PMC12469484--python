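"""Model fitting, evaluation, bootstrap CIs and importance analyses.

Three predictors of daily admission counts are compared:

* **GAM** — Poisson generalized additive model with log link: linear
  terms for the exposure lags and demographic counts plus a penalised
  B-spline smoother of dimension 50 on the day index for the long-term
  temporal trend (statsmodels ``GLMGam``).
* **RF** — random forest regression, 5000 trees, ``mtry = 3`` candidate
  variables per split, leaf size 5 (the regression defaults of the
  reference R implementation).
* **XGB** — gradient boosting, 100 trees of depth 3, learning rate
  0.05, gamma 0, colsample_bytree 0.8, subsample 0.8, min_child_weight 1.

Evaluation: seeded random 80/20 train/test split, R²/RMSE/MAE on the
held-out set, exhaustive grid search by mean 10-fold CV RMSE, and a
bootstrap that resamples the full table with replacement, re-splits and
refits each iteration, yielding empirical percentile 95% CIs.

Importance: permutation %IncMSE on held-out data (RF), normalised total
Gain (XGB), GAM Wald coefficient table, and mean-|SHAP| summaries for
the tree ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from statsmodels.gam.api import BSplines, GLMGam
import xgboost as xgb

from .features import DEMOGRAPHIC_COLUMNS
from .treeshap import forest_shap_values, shap_base_value

__all__ = [
    "RFSpec",
    "XGBSpec",
    "GAMSpec",
    "SplitPlan",
    "Metrics",
    "FittedModel",
    "split_train_test",
    "compute_metrics",
    "fit_model",
    "grid_search_cv",
    "bootstrap_metrics",
    "permutation_importance",
    "gain_importance",
    "shap_summary",
    "evaluate_models",
]


class UndefinedR2Error(ValueError):
    """R² is undefined when the observed values are constant."""


class FamilyMismatchError(ValueError):
    """Response incompatible with the Poisson family (negative/non-integer)."""


class BootstrapInstabilityError(RuntimeError):
    """More than 5% of bootstrap resamples were degenerate."""


@dataclass(frozen=True)
class RFSpec:
    kind: str = "RF"
    n_trees: int = 5000
    mtry: int = 3
    min_samples_leaf: int = 5

    def __post_init__(self):
        if self.n_trees < 1 or self.mtry < 1:
            raise ValueError("RF hyperparameters out of range")


@dataclass(frozen=True)
class XGBSpec:
    kind: str = "XGB"
    n_trees: int = 100
    max_depth: int = 3
    learning_rate: float = 0.05
    gamma: float = 0.0
    colsample_bytree: float = 0.8
    subsample: float = 0.8
    min_child_weight: float = 1.0

    def __post_init__(self):
        if not (0 < self.learning_rate <= 1) or self.n_trees < 0:
            raise ValueError("XGB hyperparameters out of range")


@dataclass(frozen=True)
class GAMSpec:
    kind: str = "GAM"
    family: str = "poisson"
    link: str = "log"
    time_basis_df: int = 50
    alpha: float = 0.0  # smoothing penalty weight on the time smoother

    def __post_init__(self):
        if self.time_basis_df < 4:
            raise ValueError("GAM basis dimension out of range")


@dataclass(frozen=True)
class SplitPlan:
    train_fraction: float = 0.8
    cv_folds: int = 10
    seed: int = 0


@dataclass(frozen=True)
class Metrics:
    r2: float
    rmse: float
    mae: float


def split_train_test(
    table: pd.DataFrame, plan: SplitPlan, min_rows: int = 50
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random 80/20 row split (no temporal blocking)."""
    n = len(table)
    if n < min_rows:
        raise ValueError(f"need at least {min_rows} usable rows, got {n}")
    rng = np.random.default_rng(plan.seed)
    perm = rng.permutation(n)
    n_train = int(round(plan.train_fraction * n))
    train = table.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    test = table.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    return train, test


def compute_metrics(y_true, y_pred) -> Metrics:
    """R², RMSE, MAE.

    R² = 1 - SSE/SST with the mean taken over the evaluated sample;
    negative values indicate a fit worse than the sample mean.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must have equal length >= 2")
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedR2Error("R² undefined for constant observed values")
    sse = float(np.sum((y_true - y_pred) ** 2))
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    mae = float(np.mean(np.abs(y_true - y_pred)))
    return Metrics(r2=1.0 - sse / sst, rmse=rmse, mae=mae)


@dataclass
class FittedModel:
    kind: str
    spec: object
    feature_columns: list[str]
    response: str
    day_column: str | None
    _predict: object
    model: object
    summary: dict = field(default_factory=dict)

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        return self._predict(frame)


def _fit_rf(spec: RFSpec, train, features, response, seed) -> FittedModel:
    rf = RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_features=min(spec.mtry, len(features)),
        min_samples_leaf=spec.min_samples_leaf,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(train[features].to_numpy(), train[response].to_numpy(dtype=float))
    return FittedModel(
        kind="RF", spec=spec, feature_columns=features, response=response,
        day_column=None,
        _predict=lambda df: rf.predict(df[features].to_numpy()),
        model=rf, summary={"hyperparameters": asdict(spec)},
    )


def _fit_xgb(spec: XGBSpec, train, features, response, seed) -> FittedModel:
    booster = xgb.XGBRegressor(
        n_estimators=spec.n_trees,
        max_depth=spec.max_depth,
        learning_rate=spec.learning_rate,
        gamma=spec.gamma,
        colsample_bytree=spec.colsample_bytree,
        subsample=spec.subsample,
        min_child_weight=spec.min_child_weight,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
    )
    booster.fit(train[features].to_numpy(), train[response].to_numpy(dtype=float))
    return FittedModel(
        kind="XGB", spec=spec, feature_columns=features, response=response,
        day_column=None,
        # boosted sums can dip below zero; counts cannot
        _predict=lambda df: np.clip(booster.predict(df[features].to_numpy()), 0.0, None),
        model=booster, summary={"hyperparameters": asdict(spec)},
    )


def _fit_gam(spec: GAMSpec, train, features, response, day_column, seed) -> FittedModel:
    y = train[response].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise FamilyMismatchError("Poisson GAM requires non-negative integer counts")
    x_day = train[day_column].to_numpy(dtype=float)[:, None]
    smoother = BSplines(x_day, df=[spec.time_basis_df], degree=[3])
    exog = sm.add_constant(train[features].to_numpy(), has_constant="add")
    model = GLMGam(
        y, exog=exog, smoother=smoother, alpha=spec.alpha,
        family=sm.families.Poisson(),
    )
    res = model.fit()
    lo, hi = float(x_day.min()), float(x_day.max())
    names = ["const"] + list(features)

    def predict(df: pd.DataFrame) -> np.ndarray:
        ex = sm.add_constant(df[features].to_numpy(), has_constant="add")
        # spline basis is defined on the training day range; clip to it
        xd = np.clip(df[day_column].to_numpy(dtype=float), lo, hi)[:, None]
        return np.asarray(res.predict(exog=ex, exog_smooth=xd))

    k = len(names)
    coef_table = pd.DataFrame(
        {
            "coefficient": res.params[:k],
            "std_err": res.bse[:k],
            "p_value": res.pvalues[:k],
        },
        index=names,
    )
    return FittedModel(
        kind="GAM", spec=spec, feature_columns=features, response=response,
        day_column=day_column, _predict=predict, model=res,
        summary={
            "hyperparameters": asdict(spec),
            "coefficients": coef_table,
            "p_value_type": "Wald",
        },
    )


def fit_model(
    spec,
    train: pd.DataFrame,
    feature_columns: list[str],
    response: str = "admissions",
    day_column: str = "day_index",
    seed: int = 0,
) -> FittedModel:
    """Fit one model spec on the training rows; returns a predictor whose
    outputs are non-negative (GAM predicts on the response scale)."""
    if spec.kind == "RF":
        return _fit_rf(spec, train, list(feature_columns), response, seed)
    if spec.kind == "XGB":
        return _fit_xgb(spec, train, list(feature_columns), response, seed)
    if spec.kind == "GAM":
        return _fit_gam(spec, train, list(feature_columns), response, day_column, seed)
    raise ValueError(f"unknown model kind: {spec.kind!r}")


def _complexity(spec) -> tuple:
    """Tie-break key: fewer trees first, then shallower."""
    trees = getattr(spec, "n_trees", 0)
    depth = getattr(spec, "max_depth", 0)
    return (trees, depth)


def grid_search_cv(
    grid: list,
    train: pd.DataFrame,
    feature_columns: list[str],
    response: str = "admissions",
    day_column: str = "day_index",
    folds: int = 10,
    seed: int = 0,
):
    """Exhaustive grid search by mean k-fold CV RMSE; ties break toward
    the simpler model (fewer trees, then shallower)."""
    if not grid:
        raise ValueError("grid must be non-empty")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    results = []
    idx = np.arange(len(train))
    for spec in grid:
        rmses = []
        for tr, te in kf.split(idx):
            fitted = fit_model(
                spec, train.iloc[tr], feature_columns, response, day_column, seed=seed
            )
            pred = fitted.predict(train.iloc[te])
            y = train.iloc[te][response].to_numpy(dtype=float)
            rmses.append(float(np.sqrt(np.mean((y - pred) ** 2))))
        results.append((float(np.mean(rmses)), spec))
    best_rmse = min(r for r, _ in results)
    candidates = [s for r, s in results if r == best_rmse]
    best = min(candidates, key=_complexity)
    return best, results


def bootstrap_metrics(
    spec,
    table: pd.DataFrame,
    feature_columns: list[str],
    response: str = "admissions",
    day_column: str = "day_index",
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Percentile bootstrap CIs for R²/RMSE/MAE.

    Each iteration draws ``len(table)`` rows with replacement as the
    training resample and evaluates on the out-of-bag rows (those the
    resample missed, ~37% of the table), refitting and recomputing all
    metrics; CIs are the empirical ``(1 - level)/2`` percentiles.  This
    propagates sampling variability without letting duplicated rows
    appear on both sides of the fit/evaluate divide.  Degenerate
    resamples (constant response on either side) are skipped and
    counted; more than 5% skips raises
    :class:`BootstrapInstabilityError`.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    master = np.random.default_rng(seed)
    iter_seeds = master.integers(0, 2**31 - 1, size=n_boot)
    records = {"r2": [], "rmse": [], "mae": []}
    skipped = 0
    n = len(table)
    for it in range(n_boot):
        rng = np.random.default_rng(iter_seeds[it])
        rows = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), rows)
        if len(oob) < 2:
            skipped += 1
            continue
        tr = table.iloc[rows].reset_index(drop=True)
        te = table.iloc[oob].reset_index(drop=True)
        if tr[response].nunique() < 2 or te[response].nunique() < 2:
            skipped += 1
            continue
        fitted = fit_model(
            spec, tr, feature_columns, response, day_column, seed=int(iter_seeds[it])
        )
        m = compute_metrics(te[response].to_numpy(dtype=float), fitted.predict(te))
        records["r2"].append(m.r2)
        records["rmse"].append(m.rmse)
        records["mae"].append(m.mae)
    if skipped > 0.05 * n_boot:
        raise BootstrapInstabilityError(
            f"{skipped}/{n_boot} degenerate bootstrap resamples"
        )
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    out = {"n_boot": n_boot, "n_skipped": skipped, "ci_level": ci_level}
    for name, vals in records.items():
        arr = np.asarray(vals)
        out[name] = {
            "ci_low": float(np.quantile(arr, lo_q)),
            "ci_high": float(np.quantile(arr, hi_q)),
            "mean": float(arr.mean()),
            "min": float(arr.min()),
            "max": float(arr.max()),
        }
    return out


def permutation_importance(
    fitted: FittedModel,
    test: pd.DataFrame,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.Series:
    """%IncMSE on held-out rows.

    For each variable: ``100 * (MSE_permuted - MSE_base) / MSE_base``,
    averaged over ``n_repeats`` seeded permutations of that column.
    """
    y = test[fitted.response].to_numpy(dtype=float)
    base_mse = float(np.mean((y - fitted.predict(test)) ** 2))
    rng = np.random.default_rng(seed)
    out = {}
    for col in fitted.feature_columns:
        incs = []
        for _ in range(n_repeats):
            shuffled = test.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            mse = float(np.mean((y - fitted.predict(shuffled)) ** 2))
            incs.append(100.0 * (mse - base_mse) / base_mse)
        out[col] = float(np.mean(incs))
    return pd.Series(out, name="pct_inc_mse")


def gain_importance(fitted: FittedModel) -> pd.Series:
    """Normalised total Gain per variable for a boosted model.

    Returns an empty series for a model with no trees; features never
    used in a split get gain 0.
    """
    if fitted.kind != "XGB":
        raise ValueError("gain importance is defined for boosted tree models")
    booster = fitted.model.get_booster()
    try:
        raw = booster.get_score(importance_type="total_gain")
    except xgb.core.XGBoostError:
        raw = {}
    if not raw:
        return pd.Series(dtype=float, name="gain")
    # xgboost names features f0, f1, ... in column order
    gains = np.zeros(len(fitted.feature_columns))
    for key, val in raw.items():
        gains[int(key[1:])] = val
    gains /= gains.sum()
    return pd.Series(gains, index=fitted.feature_columns, name="gain")


def shap_summary(
    fitted: FittedModel,
    test: pd.DataFrame,
    max_rows: int | None = None,
    seed: int = 0,
    return_matrix: bool = False,
):
    """Mean-|SHAP| per variable on (a sample of) the held-out rows.

    Exact tree-path-dependent attributions: xgboost's built-in
    ``pred_contribs`` for XGB, in-package TreeSHAP for the RF.  Both
    satisfy local accuracy (base value + attributions = prediction).
    """
    if fitted.kind not in ("RF", "XGB"):
        raise ValueError("SHAP summaries are supported for tree-based models only")
    frame = test
    if max_rows is not None and len(test) > max_rows:
        rng = np.random.default_rng(seed)
        frame = test.iloc[np.sort(rng.choice(len(test), size=max_rows, replace=False))]
    X = frame[fitted.feature_columns].to_numpy(dtype=float)
    if fitted.kind == "XGB":
        dm = xgb.DMatrix(X, feature_names=[f"f{i}" for i in range(X.shape[1])])
        contribs = fitted.model.get_booster().predict(dm, pred_contribs=True)
        phi, base = contribs[:, :-1], float(contribs[0, -1])
    else:
        phi = forest_shap_values(fitted.model, X)
        base = shap_base_value(fitted.model)
    summary = pd.Series(
        np.mean(np.abs(phi), axis=0), index=fitted.feature_columns, name="mean_abs_shap"
    )
    if return_matrix:
        return summary, phi, base
    return summary


def evaluate_models(
    table: pd.DataFrame,
    feature_columns: list[str] | None = None,
    response: str = "admissions",
    day_column: str = "day_index",
    specs: list | None = None,
    plan: SplitPlan | None = None,
    n_boot: int = 1000,
    shap_max_rows: int = 150,
) -> dict:
    """Full three-model comparison: point metrics, bootstrap CIs and
    importance tables.  Returns a report dictionary."""
    plan = plan or SplitPlan()
    specs = specs or [GAMSpec(), RFSpec(), XGBSpec()]
    if feature_columns is None:
        feature_columns = [
            c for c in table.columns
            if c not in (response, "date", day_column)
        ]
    train, test = split_train_test(table, plan)
    report: dict = {"split": asdict(plan), "models": {}}
    for spec in specs:
        fitted = fit_model(
            spec, train, feature_columns, response, day_column, seed=plan.seed
        )
        metrics = compute_metrics(
            test[response].to_numpy(dtype=float), fitted.predict(test)
        )
        entry: dict = {
            "hyperparameters": asdict(spec),
            "metrics": asdict(metrics),
            "bootstrap": bootstrap_metrics(
                spec, table, feature_columns, response, day_column,
                n_boot=n_boot, seed=plan.seed,
            ),
        }
        if spec.kind == "RF":
            entry["pct_inc_mse"] = permutation_importance(
                fitted, test, seed=plan.seed
            )
            entry["mean_abs_shap"] = shap_summary(
                fitted, test, max_rows=shap_max_rows, seed=plan.seed
            )
        elif spec.kind == "XGB":
            entry["gain"] = gain_importance(fitted)
            entry["mean_abs_shap"] = shap_summary(
                fitted, test, max_rows=shap_max_rows, seed=plan.seed
            )
        elif spec.kind == "GAM":
            entry["coefficients"] = fitted.summary["coefficients"]
        report["models"][spec.kind] = entry
    # model comparison needs identical evaluation rows; record them once
    report["n_rows"] = len(table)
    report["n_train"] = len(train)
    report["n_test"] = len(test)
    report["feature_columns"] = list(feature_columns)
    return report
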