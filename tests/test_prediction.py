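"""Preprocessing, PCA/PCR, grid-search tuning and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

from plotpheno import (
    RootYieldModel,
    SplitPlan,
    SyntheticFieldSpec,
    evaluate,
    generate_ground_truth,
    pcr_regression,
    preprocess,
    reduce_features,
    tune_and_fit,
)
from plotpheno.errors import PlotPhenoError
from plotpheno.prediction import split_by_replication


# ----------------------------------------------------------- preprocessing

def test_normal_feature_lambda_near_one(rng):
    df = pd.DataFrame({"x": rng.normal(5, 1, 800)})
    _, state = preprocess(df)
    assert state.transforms["x"].lmbda == pytest.approx(1.0, abs=0.35)


def test_lognormal_feature_lambda_near_zero(rng):
    df = pd.DataFrame({"x": np.exp(rng.normal(0, 1, 500))})
    _, state = preprocess(df)
    assert state.transforms["x"].lmbda == pytest.approx(0.0, abs=0.2)


def test_train_bounds_applied_to_test_without_reclipping(rng):
    train = pd.DataFrame({"x": rng.uniform(1, 2, 100)})
    t_train, state = preprocess(train)
    assert t_train["x"].min() == pytest.approx(-1.0)
    assert t_train["x"].max() == pytest.approx(1.0)
    test = pd.DataFrame({"x": [0.5, 3.0]})  # outside the training range
    t_test, _ = preprocess(test, state=state)
    assert t_test["x"].iloc[0] < -1.0
    assert t_test["x"].iloc[1] > 1.0


def test_constant_feature_skipped_with_warning(rng, caplog):
    import logging
    df = pd.DataFrame({"c": np.full(50, 3.0), "x": rng.normal(5, 1, 50)})
    with caplog.at_level(logging.WARNING, logger="plotpheno.prediction"):
        out, state = preprocess(df)
    assert state.transforms["c"].lmbda is None
    np.testing.assert_array_equal(out["c"], df["c"])
    assert any("constant" in r.message for r in caplog.records)


# ------------------------------------------------------------- reduction

def test_rank_one_data_explains_everything(rng):
    u = rng.normal(size=100)
    df = pd.DataFrame({"a": u, "b": 2 * u})
    red, _ = reduce_features(df, "PCA", 2)
    np.testing.assert_allclose(red.explained_variance_ratio, [1.0, 0.0],
                               atol=1e-12)


def test_full_rank_ratios_sum_to_one(rng):
    df = pd.DataFrame(rng.normal(size=(60, 5)))
    red, _ = reduce_features(df, "PCA", 5)
    assert red.explained_variance_ratio.sum() == pytest.approx(1.0)


def test_pca_matches_eigendecomposition_oracle(rng):
    """Ratios and loadings equal a direct spectral decomposition (up to sign)."""
    X = rng.normal(size=(100, 20))
    df = pd.DataFrame(X)
    red, scores = reduce_features(df, "PCA", 20)

    C = np.cov(X - X.mean(axis=0), rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    np.testing.assert_allclose(red.explained_variance_ratio,
                               evals / evals.sum(), atol=1e-8)
    for k in range(20):
        dot = abs(np.dot(red.loadings[k], evecs[:, k]))
        assert dot == pytest.approx(1.0, abs=1e-8)


def test_n_components_out_of_range_rejected(rng):
    df = pd.DataFrame(rng.normal(size=(10, 3)))
    with pytest.raises(PlotPhenoError):
        reduce_features(df, "PCA", 7)


def test_pcr_with_all_components_equals_ols(rng):
    """PCA rotation is invertible: PCR on all scores reproduces full OLS."""
    from sklearn.linear_model import LinearRegression

    X = rng.normal(size=(80, 6))
    beta = rng.normal(size=6)
    y = X @ beta + rng.normal(0, 0.5, 80)
    df = pd.DataFrame(X)
    red, scores = reduce_features(df, "PCR", 6)
    pcr = pcr_regression(scores, y)
    ols = LinearRegression().fit(X, y)
    np.testing.assert_allclose(pcr.predict(scores.to_numpy()),
                               ols.predict(X), atol=1e-6)


# ---------------------------------------------------------------- tuning

def test_degenerate_grid_returns_its_single_point(rng):
    X = pd.DataFrame(rng.normal(size=(60, 3)))
    y = X.iloc[:, 0] + rng.normal(0, 0.1, 60)
    model, params, _ = tune_and_fit(X, y, "kNN",
                                    grid={"n_neighbors": [7]}, seed=0)
    assert params == {"n_neighbors": 7}


def test_knn_with_k_equal_n_train_predicts_the_mean(rng):
    X = pd.DataFrame(rng.normal(size=(40, 2)))
    y = rng.normal(10, 2, 40)
    model, _, _ = tune_and_fit(
        X, y, "kNN", grid={"n_neighbors": [40], "weights": ["uniform"]}, seed=0)
    pred = model.predict(rng.normal(size=(5, 2)))
    np.testing.assert_allclose(pred, np.mean(y), atol=1e-9)


def test_empty_grid_rejected(rng):
    X = pd.DataFrame(rng.normal(size=(30, 2)))
    with pytest.raises(PlotPhenoError):
        tune_and_fit(X, np.zeros(30), "SVM", grid={"C": []})


# ------------------------------------------------------------- evaluation

def test_evaluation_identities(rng):
    y = rng.normal(20, 3, 50)
    perfect = evaluate(y, y)
    assert (perfect.r2, perfect.rmse, perfect.rrmse) == (1.0, 0.0, 0.0)
    mean_model = evaluate(y, np.full_like(y, y.mean()))
    assert mean_model.r2 == pytest.approx(0.0, abs=1e-12)


def test_evaluation_matches_formula_oracle(rng):
    y = rng.normal(20, 3, 200)
    yhat = y + rng.normal(0, 2, 200)
    e = evaluate(y, yhat)
    ss_res = sum((a - b) ** 2 for a, b in zip(y, yhat))
    ss_tot = sum((a - np.mean(y)) ** 2 for a in y)
    assert e.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-9)
    assert e.rmse == pytest.approx((ss_res / len(y)) ** 0.5, abs=1e-9)
    assert e.rrmse == pytest.approx(100 * e.rmse / np.mean(y), abs=1e-9)


def test_constant_yield_rejected():
    with pytest.raises(PlotPhenoError):
        evaluate(np.ones(10), np.zeros(10))


def test_rrmse_consistent_with_common_mean(rng):
    """RMSE x 100 / RRMSE recovers the same mean yield across models."""
    y = rng.normal(30, 4, 100)
    implied = set()
    for sd in (1.0, 2.0, 4.0):
        e = evaluate(y, y + rng.normal(0, sd, 100))
        implied.add(round(e.rmse * 100 / e.rrmse, 9))
    assert len(implied) == 1


# ------------------------------------------------------ model/results API

@pytest.fixture(scope="module")
def yield_fit():
    spec = SyntheticFieldSpec(seed=0, plot_rows=8, plot_cols=10)
    gt = generate_ground_truth(spec)
    model = RootYieldModel.from_dataframe(
        gt, feature_cols=["true_ndvi", "true_canopy_volume", "AGB", "CH", "LAI"],
        methods=("kNN",), n_components=4)
    return spec, gt, model.fit(seed=0)


def test_split_respects_replication_structure(yield_fit):
    spec, gt, res = yield_fit
    assert res.plan.test_rep not in res.plan.train_reps
    train, test, _ = split_by_replication(gt["replication"], res.plan)
    assert not (train & test).any()
    assert (train | test).all()


def test_results_carry_all_splits_and_summary(yield_fit):
    _, _, res = yield_fit
    frame = res.to_frame()
    assert set(frame["split"]) == {"validation", "test"}
    assert set(frame["reduction"]) == {"PCA", "PCR"}
    assert (frame["RMSE"] >= 0).all()
    assert (frame["R2"] <= 1).all()
    text = res.summary()
    assert "kNN" in text and "validation" in text and "test" in text


def test_no_train_test_leakage(yield_fit):
    """Preprocessing state is fitted on train rows only, then reused."""
    spec, gt, res = yield_fit
    train, _, _ = split_by_replication(gt["replication"], res.plan)
    state = res.preprocess_state
    tr = gt.loc[train, ["true_ndvi", "true_canopy_volume", "AGB", "CH", "LAI"]]
    t_tr, _ = preprocess(tr, state=state)
    # train rows reproduce exact [-1, 1] bounds under the stored state
    assert t_tr.min().min() == pytest.approx(-1.0)
    assert t_tr.max().max() == pytest.approx(1.0)


def test_fit_is_reproducible_under_fixed_seed():
    spec = SyntheticFieldSpec(seed=2, plot_rows=6, plot_cols=8)
    gt = generate_ground_truth(spec)
    def run():
        m = RootYieldModel.from_dataframe(
            gt, feature_cols=["true_ndvi", "true_canopy_volume"],
            methods=("RF",), reductions=("PCA",), n_components=2)
        return m.fit(seed=5).to_frame()
    pd.testing.assert_frame_equal(run(), run())


def test_overlapping_split_plan_rejected():
    with pytest.raises(PlotPhenoError):
        SplitPlan(train_reps=("R1", "R2"), test_rep="R1")
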