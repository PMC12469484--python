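"""Model fitting, metric, bootstrap and importance tests."""

import numpy as np
import pandas as pd
import pytest

from sahelheat.models import (
    GAMSpec,
    RFSpec,
    SplitPlan,
    UndefinedR2Error,
    FamilyMismatchError,
    XGBSpec,
    bootstrap_metrics,
    compute_metrics,
    fit_model,
    gain_importance,
    grid_search_cv,
    permutation_importance,
    shap_summary,
    split_train_test,
)


def toy_table(n=200, seed=0, p=3, signal=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    mu = 2.0 + (1.5 * X[:, 0] if signal else 0.0)
    y = mu + rng.normal(0, 0.5, size=n)
    frame = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    frame["admissions"] = np.round(np.abs(y)).astype(int)
    frame["y_cont"] = y
    frame["day_index"] = np.arange(n, dtype=float)
    return frame


# ---------------------------------------------------------------------------
# Split

def test_split_sizes_80_20():
    table = toy_table(100)
    train, test = split_train_test(table, SplitPlan(seed=0))
    assert len(train) == 80 and len(test) == 20
    assert len(pd.concat([train, test])) == 100


def test_split_deterministic_and_seed_sensitive():
    table = toy_table(100)
    a1, b1 = split_train_test(table, SplitPlan(seed=5))
    a2, b2 = split_train_test(table, SplitPlan(seed=5))
    pd.testing.assert_frame_equal(a1, a2)
    pd.testing.assert_frame_equal(b1, b2)
    diff = 0
    for s in range(100):
        x, _ = split_train_test(table, SplitPlan(seed=s))
        y, _ = split_train_test(table, SplitPlan(seed=s + 1000))
        diff += not x.equals(y)
    assert diff >= 99  # different seeds give different partitions


def test_split_rejects_tiny_tables():
    with pytest.raises(ValueError):
        split_train_test(toy_table(30), SplitPlan(seed=0))


# ---------------------------------------------------------------------------
# Metrics

def test_metrics_perfect_fit():
    m = compute_metrics([1, 2, 3], [1, 2, 3])
    assert (m.r2, m.rmse, m.mae) == (1.0, 0.0, 0.0)


def test_metrics_hand_computed_four_point_case():
    m = compute_metrics([0, 0, 4, 4], [1, 1, 3, 3])
    assert m.mae == pytest.approx(1.0)
    assert m.rmse == pytest.approx(1.0)
    assert m.r2 == pytest.approx(0.75)


def test_metrics_mean_predictor_gives_zero_r2():
    y = np.array([1.0, 2.0, 3.0, 6.0])
    m = compute_metrics(y, np.full(4, y.mean()))
    assert m.r2 == pytest.approx(0.0)


def test_metrics_constant_truth_rejected():
    with pytest.raises(UndefinedR2Error):
        compute_metrics([2, 2, 2], [1, 2, 3])


def test_rmse_at_least_mae_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(50):
        y = rng.normal(size=30)
        p = rng.normal(size=30)
        m = compute_metrics(y, p)
        assert m.rmse >= m.mae >= 0.0
        assert m.r2 <= 1.0


# ---------------------------------------------------------------------------
# Model fits

def test_gam_recovers_poisson_coefficients():
    """log mu = 0.5 + 0.03 x: both coefficients recovered within +-3 SE
    at n = 1500."""
    rng = np.random.default_rng(7)
    n = 1500
    x = rng.uniform(0, 30, size=n)
    y = rng.poisson(np.exp(0.5 + 0.03 * x))
    frame = pd.DataFrame({"x": x, "admissions": y, "day_index": np.arange(n, dtype=float)})
    fitted = fit_model(GAMSpec(time_basis_df=10), frame, ["x"], seed=0)
    co = fitted.summary["coefficients"]
    assert abs(co.loc["const", "coefficient"] - 0.5) < 3 * co.loc["const", "std_err"]
    assert abs(co.loc["x", "coefficient"] - 0.03) < 3 * co.loc["x", "std_err"]
    assert fitted.summary["p_value_type"] == "Wald"


def test_gam_rejects_non_count_response():
    frame = toy_table(100)
    frame["admissions"] = frame["admissions"].astype(float) + 0.5
    with pytest.raises(FamilyMismatchError):
        fit_model(GAMSpec(time_basis_df=8), frame, ["x0"], seed=0)


def test_rf_on_pure_noise_has_no_skill():
    """RF test R^2 <= 0.1 on no-signal data (10 seeds, n = 1000)."""
    for s in range(10):
        table = toy_table(1000, seed=s, signal=False)
        train, test = split_train_test(table, SplitPlan(seed=s))
        fitted = fit_model(
            RFSpec(n_trees=100), train, ["x0", "x1", "x2"], seed=s
        )
        m = compute_metrics(test["admissions"], fitted.predict(test))
        assert m.r2 <= 0.1


def test_predictions_are_non_negative(feature_table, model_features):
    train, test = split_train_test(feature_table, SplitPlan(seed=0))
    for spec in (GAMSpec(), RFSpec(n_trees=50), XGBSpec(n_trees=50)):
        fitted = fit_model(spec, train, model_features, seed=0)
        assert (fitted.predict(test) >= 0).all()


def test_hyperparameters_echoed_in_report():
    spec = XGBSpec()
    table = toy_table(120)
    fitted = fit_model(spec, table, ["x0", "x1"], seed=0)
    hp = fitted.summary["hyperparameters"]
    assert hp["n_trees"] == 100
    assert hp["max_depth"] == 3
    assert hp["learning_rate"] == 0.05
    assert hp["gamma"] == 0.0
    assert hp["colsample_bytree"] == 0.8
    assert hp["subsample"] == 0.8
    assert hp["min_child_weight"] == 1.0
    assert RFSpec().n_trees == 5000 and RFSpec().mtry == 3
    assert GAMSpec().time_basis_df == 50 and GAMSpec().family == "poisson"


def test_invalid_hyperparameters_rejected():
    with pytest.raises(ValueError):
        RFSpec(n_trees=0)
    with pytest.raises(ValueError):
        XGBSpec(learning_rate=0.0)


# ---------------------------------------------------------------------------
# Grid search

def test_grid_search_single_point():
    table = toy_table(150)
    best, results = grid_search_cv(
        [XGBSpec(n_trees=20)], table, ["x0", "x1", "x2"], folds=5, seed=0
    )
    assert best == XGBSpec(n_trees=20)
    assert len(results) == 1


def test_grid_search_prefers_true_complexity():
    """A grid containing the right depth for an additive-step signal
    selects it in most seeded replicates."""
    wins = 0
    for s in range(10):
        rng = np.random.default_rng(s)
        n = 400
        X = rng.normal(size=(n, 2))
        y = np.round(np.abs(3 + 2.0 * (X[:, 0] > 0) + rng.normal(0, 0.3, n))).astype(int)
        table = pd.DataFrame(X, columns=["x0", "x1"])
        table["admissions"] = y
        table["day_index"] = np.arange(n, dtype=float)
        grid = [
            XGBSpec(n_trees=50, max_depth=1),
            XGBSpec(n_trees=50, max_depth=6),
        ]
        best, _ = grid_search_cv(grid, table, ["x0", "x1"], folds=5, seed=s)
        wins += best.max_depth == 1
    assert wins >= 7


def test_grid_search_cv_reproducible():
    table = toy_table(150)
    grid = [XGBSpec(n_trees=10), XGBSpec(n_trees=30)]
    b1, r1 = grid_search_cv(grid, table, ["x0", "x1"], folds=5, seed=4)
    b2, r2 = grid_search_cv(grid, table, ["x0", "x1"], folds=5, seed=4)
    assert b1 == b2
    assert [a for a, _ in r1] == [a for a, _ in r2]


# ---------------------------------------------------------------------------
# Bootstrap

def test_bootstrap_deterministic_given_seed(feature_table, model_features):
    kwargs = dict(n_boot=100, seed=9)
    a = bootstrap_metrics(XGBSpec(n_trees=30), feature_table, model_features, **kwargs)
    b = bootstrap_metrics(XGBSpec(n_trees=30), feature_table, model_features, **kwargs)
    assert a == b  # bit-identical CIs


def test_bootstrap_ci_contains_point_estimate(feature_table, model_features):
    train, test = split_train_test(feature_table, SplitPlan(seed=2))
    fitted = fit_model(XGBSpec(n_trees=50), train, model_features, seed=2)
    m = compute_metrics(test["admissions"], fitted.predict(test))
    boot = bootstrap_metrics(
        XGBSpec(n_trees=50), feature_table, model_features, n_boot=150, seed=2
    )
    assert boot["r2"]["ci_low"] <= m.r2 <= boot["r2"]["ci_high"]
    assert boot["rmse"]["ci_low"] <= m.rmse <= boot["rmse"]["ci_high"]


def test_bootstrap_cis_are_nested(feature_table, model_features):
    wide = bootstrap_metrics(
        XGBSpec(n_trees=30), feature_table, model_features,
        n_boot=150, seed=3, ci_level=0.95,
    )
    narrow = bootstrap_metrics(
        XGBSpec(n_trees=30), feature_table, model_features,
        n_boot=150, seed=3, ci_level=0.90,
    )
    for metric in ("r2", "rmse", "mae"):
        assert wide[metric]["ci_low"] <= narrow[metric]["ci_low"]
        assert narrow[metric]["ci_high"] <= wide[metric]["ci_high"]


def test_bootstrap_rejects_too_few_iterations(feature_table, model_features):
    with pytest.raises(ValueError):
        bootstrap_metrics(
            XGBSpec(n_trees=10), feature_table, model_features, n_boot=50
        )


# ---------------------------------------------------------------------------
# Importance

@pytest.fixture(scope="module")
def signal_fit(feature_table, model_features):
    train, test = split_train_test(feature_table, SplitPlan(seed=1))
    rf = fit_model(RFSpec(n_trees=300), train, model_features, seed=1)
    xgb_m = fit_model(XGBSpec(), train, model_features, seed=1)
    return train, test, rf, xgb_m


def test_unused_feature_has_near_zero_pct_inc_mse():
    rng = np.random.default_rng(0)
    n = 500
    table = pd.DataFrame(
        {
            "x0": rng.normal(size=n),
            "unused": rng.normal(size=n),
            "admissions": np.round(np.abs(3 + rng.normal(size=n))).astype(int),
        }
    )
    table["admissions"] = (table["x0"] * 2 + 5).round().astype(int).clip(lower=0)
    train, test = split_train_test(table, SplitPlan(seed=0))
    fitted = fit_model(RFSpec(n_trees=100), train, ["x0", "unused"], seed=0)
    imp = permutation_importance(fitted, test, n_repeats=10, seed=0)
    assert abs(imp["unused"]) < 2.0
    assert imp["x0"] > 10.0


def test_true_signal_lag_ranks_first_by_pct_inc_mse(signal_fit):
    _, test, rf, _ = signal_fit
    imp = permutation_importance(rf, test, seed=1)
    assert imp.idxmax() in {"lag_3", "lag_4", "lag_5"}


def test_duplicated_feature_dilutes_importance(feature_table, model_features):
    table = feature_table.copy()
    table["lag_3_dup"] = table["lag_3"]
    train, test = split_train_test(table, SplitPlan(seed=1))
    lone = fit_model(RFSpec(n_trees=200), train, model_features, seed=1)
    dup = fit_model(
        RFSpec(n_trees=200), train, model_features + ["lag_3_dup"], seed=1
    )
    imp_lone = permutation_importance(lone, test, seed=1)
    imp_dup = permutation_importance(dup, test, seed=1)
    assert imp_dup["lag_3"] < imp_lone["lag_3"]
    assert imp_dup["lag_3_dup"] < imp_lone["lag_3"]


def test_gain_single_feature_model():
    table = toy_table(200)
    fitted = fit_model(XGBSpec(n_trees=20), table, ["x0"], seed=0)
    gain = gain_importance(fitted)
    assert list(gain.index) == ["x0"]
    assert gain["x0"] == pytest.approx(1.0)


def test_gain_zero_tree_model_is_empty():
    table = toy_table(200)
    fitted = fit_model(XGBSpec(n_trees=0), table, ["x0", "x1"], seed=0)
    assert gain_importance(fitted).empty


def test_gain_ranks_true_signal_lag_first(signal_fit):
    _, _, _, xgb_m = signal_fit
    gain = gain_importance(xgb_m)
    assert gain.idxmax() in {"lag_3", "lag_4", "lag_5"}
    assert gain.sum() == pytest.approx(1.0)


def test_shap_local_accuracy(signal_fit):
    _, test, rf, xgb_m = signal_fit
    for fitted in (rf, xgb_m):
        summary, phi, base = shap_summary(
            fitted, test, max_rows=40, seed=0, return_matrix=True
        )
        rows = test.iloc[
            np.sort(np.random.default_rng(0).choice(len(test), size=40, replace=False))
        ]
        if fitted.kind == "RF":
            pred = fitted.predict(rows)
            atol = 1e-8  # float64 attributions
        else:
            # XGB raw margin (the additive sum) before the non-negativity clip
            pred = fitted.model.predict(rows[fitted.feature_columns].to_numpy())
            atol = 1e-3  # float32 contributions from the booster
        assert np.allclose(base + phi.sum(axis=1), pred, atol=atol)
        assert (summary >= 0).all()


def test_shap_unused_feature_is_zero():
    rng = np.random.default_rng(0)
    n = 300
    table = pd.DataFrame({"x0": rng.normal(size=n), "unused": rng.normal(size=n)})
    table["admissions"] = (table["x0"] * 3 + 6).round().clip(lower=0).astype(int)
    # force the forest to never split on 'unused' by making it constant
    table2 = table.copy()
    table2["unused"] = 0.0
    fitted2 = fit_model(RFSpec(n_trees=50, mtry=2), table2, ["x0", "unused"], seed=0)
    summary = shap_summary(fitted2, table2, max_rows=50, seed=0)
    assert summary["unused"] == 0.0


def test_shap_ranking_agrees_with_permutation_on_top_variable(signal_fit):
    _, test, rf, _ = signal_fit
    imp = permutation_importance(rf, test, seed=1)
    summary = shap_summary(rf, test, max_rows=100, seed=1)
    top_cluster = {"lag_3", "lag_4", "lag_5"}
    assert imp.idxmax() in top_cluster
    assert summary.idxmax() in top_cluster


def test_shap_rejects_non_tree_model(feature_table, model_features):
    fitted = fit_model(GAMSpec(), feature_table, model_features, seed=0)
    with pytest.raises(ValueError):
        shap_summary(fitted, feature_table)
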