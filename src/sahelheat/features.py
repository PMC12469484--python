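"""Daily model matrix and cross-validated LASSO predictor selection.

The exposure of interest is the daily cumulative heatwave intensity
(``icum_daily``) together with its lags 1..7, capturing delayed health
effects up to a week after exposure.  Demographic vulnerability counts
(women, infants 0-4, seniors 65-79, seniors 80+ consulted per day) enter
as same-day covariates and are not lagged.

Selection uses the L1-penalised least-squares (LASSO) objective

    min_b  sum_i (y_i - X_i b)^2  +  lambda * sum_j |b_j|

on internally standardised predictors (zero mean, unit variance), with
lambda chosen on a 100-point log grid from lambda_max (the smallest
penalty that zeroes every coefficient) down to lambda_max * 1e-4 by
k-fold cross-validation, taking the CV-error minimum.  At lambda = 0 the
objective is ordinary least squares and is solved as such.  The final
feature set expands the top selected exposure variable with its full
lag 0..7 family, so the delayed-effect profile stays interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

__all__ = [
    "DEMOGRAPHIC_COLUMNS",
    "LAG_COLUMNS",
    "build_lags",
    "build_feature_table",
    "LassoResult",
    "lasso_select",
]

DEMOGRAPHIC_COLUMNS = ["women_count", "infants_0_4", "seniors_65_79", "seniors_80p"]
LAG_COLUMNS = ["icum_daily"] + [f"lag_{k}" for k in range(1, 8)]


class DegeneratePredictorError(ValueError):
    """A predictor column is constant and cannot be standardised."""


def build_lags(exposure: pd.DataFrame, max_lag: int = 7) -> pd.DataFrame:
    """Lag columns of the daily exposure.

    ``lag_k`` at day ``t`` is the exposure at day ``t - k``; the leading
    ``k`` entries are missing.  ``lag_0`` is the exposure itself
    (kept under its original name ``icum_daily``).
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    out = exposure[["date", "icum_daily"]].copy()
    for k in range(1, max_lag + 1):
        out[f"lag_{k}"] = out["icum_daily"].shift(k)
    return out


def build_feature_table(
    exposure: pd.DataFrame,
    admissions: pd.DataFrame,
    max_lag: int = 7,
    dropna: bool = True,
) -> pd.DataFrame:
    """Join lagged exposure with demographic counts and the response.

    Parameters
    ----------
    exposure
        ``date`` + ``icum_daily`` daily exposure series.
    admissions
        ``date`` + ``admissions`` + demographic count columns.
    dropna
        Drop the leading rows whose lags are undefined (default; they
        must not enter modelling).
    """
    lags = build_lags(exposure, max_lag=max_lag)
    table = lags.merge(admissions, on="date", how="inner")
    if (table["admissions"] < 0).any():
        raise ValueError("admissions must be non-negative")
    if dropna:
        table = table.dropna(subset=[f"lag_{k}" for k in range(1, max_lag + 1)])
    return table.reset_index(drop=True)


@dataclass
class LassoResult:
    lambda_grid: np.ndarray
    cv_error: np.ndarray
    selected_lambda: float
    coefficients: pd.Series          # standardized-scale coefficients at selected_lambda
    selected_predictors: list[str]   # nonzero-coefficient set
    final_feature_set: list[str]     # top exposure variable expanded with lags 0..7
    cv_folds: int = 10
    extra: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "lambda_grid": self.lambda_grid.tolist(),
            "cv_error": self.cv_error.tolist(),
            "selected_lambda": self.selected_lambda,
            "coefficients": self.coefficients.to_dict(),
            "selected_predictors": self.selected_predictors,
            "final_feature_set": self.final_feature_set,
            "cv_folds": self.cv_folds,
        }


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise DegeneratePredictorError("constant predictor column cannot be standardised")
    return (X - mean) / sd, mean, sd


def lasso_fit(X_std: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Coefficients minimising sum-of-squares + lam * ||b||_1 on a
    standardised design (intercept handled by centering y).

    At ``lam = 0`` the objective is ordinary least squares and is solved
    directly.  sklearn's coordinate descent minimises
    ``(1/2n)||y - Xb||^2 + alpha ||b||_1``, so ``alpha = lam / (2n)``.
    """
    n = len(y)
    yc = y - y.mean()
    if lam == 0.0:
        coef, *_ = np.linalg.lstsq(X_std, yc, rcond=None)
        return coef
    model = Lasso(alpha=lam / (2.0 * n), fit_intercept=False, max_iter=100_000, tol=1e-10)
    model.fit(X_std, yc)
    return model.coef_


def lambda_max(X_std: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is exactly zero:
    ``2 * max_j |x_j . (y - ybar)|`` for this objective scaling."""
    yc = y - y.mean()
    return 2.0 * float(np.max(np.abs(X_std.T @ yc)))


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    cv_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    n_lambdas: int = 100,
    seed: int = 0,
    exposure_columns: list[str] | None = None,
    max_lag: int = 7,
    rule: str = "min",
) -> LassoResult:
    """Cross-validated LASSO selection over the penalty path.

    ``rule`` picks the penalty from the CV curve: ``"min"`` (default)
    takes the CV-error minimum; ``"1se"`` takes the largest penalty
    whose CV error is within one standard error of the minimum (a
    sparser, more conservative choice).

    Returns the nonzero-coefficient predictors at the CV-optimal penalty
    and the final feature set: the selected exposure variable with the
    largest absolute standardised coefficient, expanded with its lags
    0..``max_lag``.  If no exposure variable survives, the exposure with
    the largest coefficient magnitude anywhere on the path is used (the
    delayed-effect profile is always reported).
    """
    X = pd.DataFrame(X)
    names = list(X.columns)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n <= cv_folds:
        raise ValueError("need more observations than CV folds")
    X_std, _, _ = _standardize(X.to_numpy(dtype=float))

    if lambda_grid is None:
        lmax = lambda_max(X_std, y)
        if lmax == 0.0:
            lmax = 1.0
        lambda_grid = np.geomspace(lmax, lmax * 1e-4, n_lambdas)
    lambda_grid = np.asarray(sorted(lambda_grid, reverse=True), dtype=float)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_mse = np.zeros((cv_folds, len(lambda_grid)))
    fold_n = np.zeros(cv_folds)
    for f, (train_idx, test_idx) in enumerate(kf.split(X_std)):
        Xtr, ytr = X_std[train_idx], y[train_idx]
        Xte, yte = X_std[test_idx], y[test_idx]
        # standardisation is refit inside each fold to avoid leakage
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        mu = Xtr.mean(axis=0)
        Xtr_s, Xte_s = (Xtr - mu) / sd, (Xte - mu) / sd
        fold_n[f] = len(test_idx)
        for i, lam in enumerate(lambda_grid):
            coef = lasso_fit(Xtr_s, ytr, lam)
            pred = Xte_s @ coef + ytr.mean()
            fold_mse[f, i] = np.mean((yte - pred) ** 2)
    cv_error = fold_mse.T @ fold_n / n

    best = int(np.argmin(cv_error))
    if rule == "1se":
        cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(cv_folds)
        within = cv_error <= cv_error[best] + cv_se[best]
        best = int(np.flatnonzero(within)[0])  # grid is descending: largest λ
    elif rule != "min":
        raise ValueError("rule must be 'min' or '1se'")
    selected_lambda = float(lambda_grid[best])
    coef = lasso_fit(X_std, y, selected_lambda)
    coefficients = pd.Series(coef, index=names)
    selected = [nm for nm, c in coefficients.items() if c != 0.0]

    if exposure_columns is None:
        exposure_columns = [nm for nm in names if nm in LAG_COLUMNS]
    exposure_sel = coefficients[
        [nm for nm in exposure_columns if nm in selected]
    ].abs()
    if len(exposure_sel):
        top_exposure = exposure_sel.idxmax()
    elif exposure_columns:
        top_exposure = coefficients[exposure_columns].abs().idxmax()
    else:
        top_exposure = None

    if top_exposure is not None:
        base = "icum_daily" if top_exposure in LAG_COLUMNS else top_exposure
        final = [base] + [f"lag_{k}" for k in range(1, max_lag + 1)]
        final = [c for c in final if c in names]
    else:
        final = selected

    return LassoResult(
        lambda_grid=lambda_grid,
        cv_error=cv_error,
        selected_lambda=selected_lambda,
        coefficients=coefficients,
        selected_predictors=selected,
        final_feature_set=final,
        cv_folds=cv_folds,
        extra={"seed": seed, "top_exposure": top_exposure},
    )
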