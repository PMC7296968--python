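"""Root-yield prediction from plot features.

Pipeline: per-feature Box-Cox (maximum-likelihood lambda, after a shift to
positivity) then min-max scaling to [-1, 1]; PCA for dimensionality
reduction; RF / SVM / kNN / ANN regressors tuned by grid search with
ten-fold cross-validation. Train/test splitting follows the field design:
whole replications train, one replication held out for testing.

The module is organised around a model/results pair:

>>> model = RootYieldModel.from_dataframe(df, target="root_yield")
>>> res = model.fit(seed=0)
>>> print(res.summary())

``RootYieldResults`` carries per-method/per-reduction R^2, RMSE and RRMSE on
the cross-validation (validation) and held-out (test) splits, the chosen
hyperparameters, and the fitted preprocessing/PCA state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold, cross_val_predict
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .errors import PlotPhenoError

log = logging.getLogger(__name__)

METHODS = ("RF", "SVM", "kNN", "ANN")
REDUCTIONS = ("PCA", "PCR")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass
class FeatureTransform:
    shift: float
    lmbda: float | None   # None: feature skipped (constant on training data)
    lo: float | None      # train bounds of the Box-Cox output
    hi: float | None


@dataclass
class PreprocessState:
    """Fitted per-feature Box-Cox + scaling parameters (train-only)."""

    transforms: dict[str, FeatureTransform] = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return list(self.transforms)


def _boxcox_apply(x: np.ndarray, lmbda: float) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        if lmbda == 0:
            return np.log(x)
        return (np.power(x, lmbda) - 1.0) / lmbda


def preprocess(features: pd.DataFrame,
               state: PreprocessState | None = None
               ) -> tuple[pd.DataFrame, PreprocessState]:
    """Shift-to-positive -> Box-Cox (ML lambda) -> min-max scale to [-1, 1].

    With ``state`` given, applies the stored training transform without
    refitting (test rows may legitimately land outside [-1, 1]; they are
    not re-clipped). Constant training features are passed through with a
    warning — the power transform is undefined for them.
    """
    numeric = features.select_dtypes(include=[np.number])
    out = {}
    if state is None:
        state = PreprocessState()
        for col in numeric.columns:
            x = numeric[col].to_numpy(dtype=np.float64)
            if np.ptp(x[np.isfinite(x)]) == 0:
                log.warning("feature %s constant on training data; skipped", col)
                state.transforms[col] = FeatureTransform(0.0, None, None, None)
                out[col] = x
                continue
            xmin = np.nanmin(x)
            shift = 0.0 if xmin > 0 else float(-xmin + 1e-6)
            transformed, lmbda = sps.boxcox(x[np.isfinite(x)] + shift)
            lo, hi = float(transformed.min()), float(transformed.max())
            state.transforms[col] = FeatureTransform(shift, float(lmbda), lo, hi)
            out[col] = _apply_one(x, state.transforms[col])
    else:
        for col in numeric.columns:
            if col not in state.transforms:
                raise PlotPhenoError(f"no stored transform for feature {col!r}")
            out[col] = _apply_one(numeric[col].to_numpy(dtype=np.float64),
                                  state.transforms[col])
    return pd.DataFrame(out, index=features.index), state


def _apply_one(x: np.ndarray, t: FeatureTransform) -> np.ndarray:
    if t.lmbda is None:
        return x
    z = _boxcox_apply(x + t.shift, t.lmbda)
    return -1.0 + 2.0 * (z - t.lo) / (t.hi - t.lo)


# ---------------------------------------------------------------------------
# dimensionality reduction
# ---------------------------------------------------------------------------

@dataclass
class ComponentReduction:
    kind: str                 # "PCA" or "PCR"
    n_components: int
    loadings: np.ndarray      # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    pca: PCA


def reduce_features(features: pd.DataFrame, kind: str = "PCA",
                    n_components: int = 4
                    ) -> tuple[ComponentReduction, pd.DataFrame]:
    """Centered PCA of the feature matrix; scores named PC1..PCk."""
    if kind not in REDUCTIONS:
        raise PlotPhenoError(f"unknown reduction {kind!r}")
    n_max = min(features.shape)
    if not 1 <= n_components <= n_max:
        raise PlotPhenoError(
            f"n_components={n_components} outside [1, {n_max}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(features.to_numpy(dtype=np.float64))
    red = ComponentReduction(kind=kind, n_components=n_components,
                             loadings=pca.components_,
                             explained_variance_ratio=pca.explained_variance_ratio_,
                             pca=pca)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return red, pd.DataFrame(scores, index=features.index, columns=cols)


def pcr_regression(scores: pd.DataFrame, y) -> LinearRegression:
    """Principal component regression: OLS on component scores."""
    return LinearRegression().fit(scores.to_numpy(dtype=np.float64),
                                  np.asarray(y, dtype=np.float64))


# ---------------------------------------------------------------------------
# model fitting and evaluation
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Replication-based split: whole reps train, one rep tests."""

    train_reps: tuple
    test_rep: object
    cv_folds: int = 10

    def __post_init__(self):
        if self.test_rep in self.train_reps:
            raise PlotPhenoError("test replication overlaps training reps")


def split_by_replication(reps: pd.Series,
                         plan: SplitPlan | None = None) -> tuple[np.ndarray, np.ndarray, SplitPlan]:
    """Boolean train/test row masks from a replication column."""
    levels = sorted(pd.unique(reps))
    if plan is None:
        if len(levels) < 2:
            raise PlotPhenoError("need >= 2 replications to split")
        plan = SplitPlan(train_reps=tuple(levels[:-1]), test_rep=levels[-1])
    train = reps.isin(plan.train_reps).to_numpy()
    test = (reps == plan.test_rep).to_numpy()
    if not (train | test).all():
        raise PlotPhenoError("split plan leaves samples unassigned")
    return train, test, plan


def default_grid(method: str, n_features: int, n_train: int) -> dict:
    """Grids centered on the published operating points for each method."""
    if method == "RF":
        mf = sorted({min(m, n_features) for m in (2, 4)})
        return {"n_estimators": [100], "max_features": mf,
                "min_samples_leaf": [1, 5]}
    if method == "SVM":
        return {"C": [0.7, 2.1, 6.3, 18.9], "kernel": ["rbf"],
                "gamma": ["scale", 0.1, 0.3]}
    if method == "kNN":
        # clip k to the smallest CV training fold so every fit is valid
        fold_n = max(1, (n_train * 9) // 10 - 1)
        ks = sorted({min(k, fold_n) for k in (5, 12, 38)})
        return {"n_neighbors": ks, "algorithm": ["ball_tree"],
                "weights": ["uniform"]}
    if method == "ANN":
        return {"hidden_layer_sizes": [(16,), (64,)]}
    raise PlotPhenoError(f"unknown method {method!r}")


def _make_estimator(method: str, seed: int):
    if method == "RF":
        return RandomForestRegressor(random_state=seed)
    if method == "SVM":
        return SVR()
    if method == "kNN":
        return KNeighborsRegressor()
    if method == "ANN":
        # single-hidden-layer perceptron trained by stochastic gradient descent
        return MLPRegressor(solver="sgd", learning_rate="adaptive",
                            activation="relu", max_iter=4000, tol=1e-6,
                            random_state=seed)
    raise PlotPhenoError(f"unknown method {method!r}")


def tune_and_fit(scores: pd.DataFrame, y, method: str,
                 grid: dict | None = None, cv_folds: int = 10,
                 seed: int = 0):
    """Grid search minimizing 10-fold CV RMSE; returns (model, params, cv)."""
    X = scores.to_numpy(dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if grid is None:
        grid = default_grid(method, X.shape[1], len(y))
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise PlotPhenoError("empty hyperparameter grid")
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(_make_estimator(method, seed), grid,
                          scoring="neg_root_mean_squared_error", cv=cv)
    search.fit(X, y)
    return search.best_estimator_, dict(search.best_params_), search


@dataclass
class ModelEvaluation:
    """R^2 / RMSE / RRMSE of one method x reduction on one split."""

    method: str
    reduction: str
    split: str            # "validation" (CV) or "test" (held-out rep)
    r2: float
    rmse: float
    rrmse: float          # percent of the mean observed yield


def evaluate(y_true, y_pred, method: str = "", reduction: str = "",
             split: str = "") -> ModelEvaluation:
    """R^2 = 1 - SS_res/SS_tot; RMSE; RRMSE = 100 * RMSE / mean(observed)."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise PlotPhenoError("R^2 undefined: observed yield has zero variance")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    return ModelEvaluation(method=method, reduction=reduction, split=split,
                           r2=1.0 - ss_res / ss_tot, rmse=rmse,
                           rrmse=100.0 * rmse / float(y_true.mean()))


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class RootYieldModel:
    """Root-yield prediction model over a plot-feature table.

    Parameters
    ----------
    features : DataFrame of numeric predictors (rows = plots/samples)
    target : Series of observed root yield
    reps : Series of replication labels, used for the train/test split
    n_components : PCA components retained (default 4, the ~80%-variance rule)
    methods, reductions : which regressors / reduction variants to fit
    """

    def __init__(self, features: pd.DataFrame, target: pd.Series,
                 reps: pd.Series, n_components: int = 4,
                 methods: tuple = METHODS, reductions: tuple = REDUCTIONS,
                 plan: SplitPlan | None = None,
                 grids: dict[str, dict] | None = None):
        if len(features) != len(target) or len(features) != len(reps):
            raise PlotPhenoError("features, target and reps lengths differ")
        self.features = features.reset_index(drop=True)
        self.target = pd.Series(np.asarray(target, dtype=np.float64))
        self.reps = pd.Series(list(reps))
        self.n_components = n_components
        self.methods = tuple(methods)
        self.reductions = tuple(reductions)
        self.plan = plan
        self.grids = grids or {}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str = "root_yield",
                       rep_col: str = "replication",
                       feature_cols: list[str] | None = None,
                       **kwargs) -> "RootYieldModel":
        if feature_cols is None:
            drop = {target, rep_col, "plot_id", "genotype", "stage",
                    "timing_point", "timestamp"}
            feature_cols = [c for c in df.columns
                            if c not in drop
                            and pd.api.types.is_numeric_dtype(df[c])]
        return cls(df[feature_cols], df[target], df[rep_col], **kwargs)

    def fit(self, seed: int = 0) -> "RootYieldResults":
        train, test, plan = split_by_replication(self.reps, self.plan)
        X_train, state = preprocess(self.features.loc[train])
        X_test, _ = preprocess(self.features.loc[test], state=state)
        y_train = self.target[train].to_numpy()
        y_test = self.target[test].to_numpy()

        n_comp = min(self.n_components, min(X_train.shape))
        red_full, scores_train = reduce_features(X_train, "PCA", n_comp)
        scores_test = pd.DataFrame(
            red_full.pca.transform(X_test.to_numpy(dtype=np.float64)),
            columns=scores_train.columns)

        # PCR variant: components re-ranked by their training correlation
        # with yield (supervised selection), then fed to the same regressors
        order_pcr = _rank_by_correlation(scores_train, y_train)

        evaluations, params, predictions = [], {}, {}
        for reduction in self.reductions:
            if reduction == "PCA":
                tr, te = scores_train, scores_test
            else:
                tr = scores_train.iloc[:, order_pcr]
                te = scores_test.iloc[:, order_pcr]
            for method in self.methods:
                model, best, search = tune_and_fit(
                    tr, y_train, method, grid=self.grids.get(method),
                    cv_folds=plan.cv_folds, seed=seed)
                cv = KFold(n_splits=plan.cv_folds, shuffle=True,
                           random_state=seed)
                y_cv = cross_val_predict(model, tr.to_numpy(), y_train, cv=cv)
                evaluations.append(evaluate(y_train, y_cv, method, reduction,
                                            "validation"))
                y_hat = model.predict(te.to_numpy())
                evaluations.append(evaluate(y_test, y_hat, method, reduction,
                                            "test"))
                params[(method, reduction)] = best
                predictions[(method, reduction)] = (y_test, y_hat)

        return RootYieldResults(model=self, plan=plan, seed=seed,
                                preprocess_state=state, reduction=red_full,
                                evaluations=evaluations, best_params=params,
                                predictions=predictions)


def _rank_by_correlation(scores: pd.DataFrame, y: np.ndarray) -> list[int]:
    corrs = []
    for j in range(scores.shape[1]):
        s = scores.iloc[:, j].to_numpy()
        c = 0.0 if np.ptp(s) == 0 else abs(np.corrcoef(s, y)[0, 1])
        corrs.append(c)
    return list(np.argsort(corrs)[::-1])


@dataclass
class RootYieldResults:
    """Fit results: metrics per method x reduction x split, plus fit state."""

    model: RootYieldModel
    plan: SplitPlan
    seed: int
    preprocess_state: PreprocessState
    reduction: ComponentReduction
    evaluations: list[ModelEvaluation]
    best_params: dict
    predictions: dict

    def to_frame(self) -> pd.DataFrame:
        rows = [{"method": e.method, "reduction": e.reduction, "split": e.split,
                 "R2": e.r2, "RMSE": e.rmse, "RRMSE": e.rrmse}
                for e in self.evaluations]
        return pd.DataFrame(rows)

    def metric(self, method: str, reduction: str, split: str) -> ModelEvaluation:
        for e in self.evaluations:
            if (e.method, e.reduction, e.split) == (method, reduction, split):
                return e
        raise KeyError((method, reduction, split))

    def summary(self) -> str:
        lines = ["Root yield model comparison",
                 f"  samples: {len(self.model.target)}  "
                 f"train reps: {list(self.plan.train_reps)}  "
                 f"test rep: {self.plan.test_rep}  "
                 f"components: {self.reduction.n_components}",
                 f"  explained variance ratio: "
                 + ", ".join(f"{v:.3f}"
                             for v in self.reduction.explained_variance_ratio),
                 "",
                 f"{'split':<12}{'method':<8}{'reduction':<11}"
                 f"{'R2':>8}{'RMSE':>10}{'RRMSE %':>10}"]
        for split in ("validation", "test"):
            for e in self.evaluations:
                if e.split == split:
                    lines.append(f"{e.split:<12}{e.method:<8}{e.reduction:<11}"
                                 f"{e.r2:>8.3f}{e.rmse:>10.3f}{e.rrmse:>10.2f}")
        return "\n".join(lines)

    def write_report(self, path) -> None:
        """Model-comparison CSV (method x reduction x split x metrics)."""
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    def plot_observed_vs_predicted(self, method: str = "RF",
                                   reduction: str = "PCA", ax=None):
        import matplotlib.pyplot as plt

        y_true, y_pred = self.predictions[(method, reduction)]
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(y_true, y_pred, s=12, alpha=0.6)
        lims = [min(y_true.min(), y_pred.min()), max(y_true.max(), y_pred.max())]
        ax.plot(lims, lims, "k--", lw=1)
        e = self.metric(method, reduction, "test")
        ax.set_xlabel("observed yield")
        ax.set_ylabel("predicted yield")
        ax.set_title(f"{method}/{reduction}: R2={e.r2:.2f} RMSE={e.rmse:.2f}")
        return ax
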