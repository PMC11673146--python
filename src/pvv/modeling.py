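"""Penalized feature selection, frequency analysis, model comparison and
the final single-feature predictor.

The inference chain mirrors a stability-selection workflow under k-fold
cross-validation: within each training fold an L1-penalized linear
regression is swept over a descending penalty grid until the number of
surviving coefficients first reaches — without exceeding — a cap of three;
selected features are counted across folds (frequency analysis) and the
most frequently selected one becomes the final model input.  Variance
inflation factors diagnose multicollinearity within each fold's selection;
four regression families (linear, random forest, support-vector,
gradient-boosted trees) are compared by validation MAE on the same folds;
and the final univariate linear model is evaluated per fold and in
aggregate (mean-over-folds and pooled) by MAE in seconds and Pearson r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools import add_constant
from xgboost import XGBRegressor

from .features import FeatureTable

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("LR", "RF", "SVM", "XGB")


class SelectionError(ValueError):
    """The penalty sweep produced no usable selection."""


def default_alpha_grid() -> np.ndarray:
    """100 log-spaced penalties, descending over [1e-3, 1e2]."""
    return np.logspace(2, -3, 100)


@dataclass(frozen=True)
class SelectionConfig:
    n_folds: int = 5
    max_features: int = 3
    alpha_grid: np.ndarray = field(default_factory=default_alpha_grid)
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        grid = np.asarray(self.alpha_grid, dtype=float)
        object.__setattr__(self, "alpha_grid", grid)
        if len(grid) == 0 or (grid <= 0).any() or (np.diff(grid) >= 0).any():
            raise ValueError("alpha_grid must be strictly decreasing and positive")
        if self.max_features < 1:
            raise ValueError("max_features must be at least 1")


@dataclass
class FoldSelection:
    fold: int
    alpha: float
    coefficients: pd.Series  # standardized-scale coefs for selected features
    vif: pd.Series | None    # None when a single feature was selected

    @property
    def features(self) -> list[str]:
        return list(self.coefficients.index)


@dataclass
class SelectionReport:
    per_fold: list[FoldSelection]
    frequency: pd.Series       # feature -> count of folds selected
    final_feature: str

    def frequency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.frequency.index, "count": self.frequency.to_numpy()}
        )


@dataclass
class EvaluationResult:
    """Cross-validated performance of a fitted predictor."""

    per_fold: pd.DataFrame     # fold, mae, pearson_r, slope
    predictions: pd.DataFrame  # subject_id, fold, actual, predicted
    mean_mae: float
    mean_r: float
    pooled_mae: float
    pooled_r: float


def _standardize(train: pd.DataFrame, other: pd.DataFrame | None = None):
    """Z-score using training-fold statistics only (no leakage)."""
    scaler = StandardScaler().fit(train.to_numpy())
    out_train = pd.DataFrame(
        scaler.transform(train.to_numpy()), index=train.index, columns=train.columns
    )
    if other is None:
        return out_train
    out_other = pd.DataFrame(
        scaler.transform(other.to_numpy()), index=other.index, columns=other.columns
    )
    return out_train, out_other


def lasso_sweep_select(
    X: pd.DataFrame, y, config: SelectionConfig | None = None
) -> tuple[float, pd.Series]:
    """Sweep the penalty grid and return the selection at the cap.

    Walking the grid from the strongest penalty downward, the chosen grid
    point is the one whose non-zero-coefficient count is in
    [1, max_features] just before the count would exceed the cap (the count
    "first approaches but does not exceed" three).  If more than
    ``max_features`` coefficients survive numerically, the largest by
    absolute value are kept.  Returns (alpha, coefficients) with
    coefficients on the standardized-feature scale.
    """
    config = config or SelectionConfig()
    y = np.asarray(y, dtype=float)
    if len(X) < config.max_features + 2:
        raise ValueError(
            f"need at least {config.max_features + 2} training subjects, got {len(X)}"
        )
    if config.max_features >= X.shape[1]:
        raise ValueError("max_features must be smaller than the number of features")
    Xs = _standardize(X) if config.standardize else X

    candidate: tuple[float, np.ndarray] | None = None
    overshoot: tuple[float, np.ndarray] | None = None
    for alpha in config.alpha_grid:
        model = Lasso(alpha=float(alpha), max_iter=100_000)
        model.fit(Xs.to_numpy(), y)
        count = int(np.count_nonzero(model.coef_))
        if count > config.max_features:
            overshoot = (float(alpha), model.coef_.copy())
            break
        if 1 <= count <= config.max_features:
            candidate = (float(alpha), model.coef_.copy())
    if candidate is None:
        if overshoot is not None:
            # grid jumped straight past the cap (near-duplicate features
            # entering together): keep the largest coefficients at that point
            candidate = overshoot
        else:
            raise SelectionError(
                "no penalty in the grid yields a non-empty selection of at "
                f"most {config.max_features} features; widen the alpha grid"
            )
    alpha, coef = candidate
    nonzero = pd.Series(coef, index=X.columns)
    nonzero = nonzero[nonzero != 0.0]
    nonzero = nonzero.reindex(
        nonzero.abs().sort_values(ascending=False).index
    ).head(config.max_features)
    return alpha, nonzero


def frequency_analysis(
    per_fold_coefficients: list[pd.Series],
) -> tuple[pd.Series, str]:
    """Count selections across folds and pick the final feature.

    The final feature has the maximal count; ties break by mean absolute
    coefficient across the folds where the feature was selected, then
    lexicographically.
    """
    if not per_fold_coefficients:
        raise ValueError("need at least one fold")
    counts: dict[str, int] = {}
    abs_sums: dict[str, float] = {}
    for coefs in per_fold_coefficients:
        for name, value in coefs.items():
            counts[name] = counts.get(name, 0) + 1
            abs_sums[name] = abs_sums.get(name, 0.0) + abs(float(value))
    frequency = pd.Series(counts).sort_values(ascending=False, kind="stable")

    def rank(name: str):
        return (-counts[name], -abs_sums[name] / counts[name], name)

    final = min(counts, key=rank)
    order = sorted(frequency.index, key=rank)
    return frequency.loc[order], final


def variance_inflation(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1/(1 - R^2_j) from regressing feature j on the others.

    Regressions include an intercept.  Perfect collinearity is reported as
    infinity rather than an arbitrarily large number.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 features")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("VIF needs more rows than features")
    exog = add_constant(X.to_numpy(), has_constant="add")
    out = {}
    for j, name in enumerate(X.columns):
        with np.errstate(divide="ignore", invalid="ignore"):
            vif = variance_inflation_factor(exog, j + 1)
        out[name] = np.inf if (not np.isfinite(vif) or vif > 1e12) else float(vif)
    return pd.Series(out)


def _folds(index, config: SelectionConfig):
    splitter = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    return list(splitter.split(np.arange(len(index))))


def run_selection(
    table: FeatureTable, config: SelectionConfig | None = None
) -> SelectionReport:
    """Per-fold penalized selection plus cross-fold frequency analysis."""
    config = config or SelectionConfig()
    X, y = table.values, table.label.to_numpy()
    per_fold = []
    for fold, (train_idx, _) in enumerate(_folds(X.index, config)):
        X_train = X.iloc[train_idx]
        alpha, coefs = lasso_sweep_select(X_train, y[train_idx], config)
        vif = None
        if len(coefs) >= 2:
            vif = variance_inflation(_standardize(X_train[coefs.index]))
        per_fold.append(
            FoldSelection(fold=fold, alpha=alpha, coefficients=coefs, vif=vif)
        )
    frequency, final = frequency_analysis([fs.coefficients for fs in per_fold])
    return SelectionReport(per_fold=per_fold, frequency=frequency, final_feature=final)


def _model_factory(family: str, seed: int):
    if family == "LR":
        return LinearRegression()
    if family == "RF":
        return RandomForestRegressor(random_state=seed)
    if family == "SVM":
        return make_pipeline(StandardScaler(), SVR())
    if family == "XGB":
        return XGBRegressor(random_state=seed, verbosity=0)
    raise ValueError(f"unknown model family {family!r}")


def compare_models(
    table: FeatureTable,
    selection: SelectionReport,
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Validation MAE of four regression families on the shared folds.

    Each family is trained on each fold's training subjects using that
    fold's selected features and scored by MAE on the fold's validation
    subjects.  Returns one row per (family, fold) plus per-family means
    (fold = "mean").
    """
    config = config or SelectionConfig()
    X, y = table.values, table.label.to_numpy()
    rows = []
    for fold, (train_idx, val_idx) in enumerate(_folds(X.index, config)):
        if len(val_idx) < 2:
            raise ValueError(f"fold {fold} has fewer than 2 validation subjects")
        feats = selection.per_fold[fold].features
        X_train, X_val = X.iloc[train_idx][feats], X.iloc[val_idx][feats]
        for family in MODEL_FAMILIES:
            model = _model_factory(family, config.seed)
            model.fit(X_train.to_numpy(), y[train_idx])
            pred = np.asarray(model.predict(X_val.to_numpy()), dtype=float)
            mae = float(np.mean(np.abs(pred - y[val_idx])))
            rows.append({"model": family, "fold": fold, "mae": mae})
    result = pd.DataFrame(rows)
    means = (
        result.groupby("model", sort=False)["mae"].mean().reset_index()
        .assign(fold="mean")
    )
    return pd.concat([result, means], ignore_index=True)[["model", "fold", "mae"]]


def fit_final_single_feature(
    table: FeatureTable,
    feature_name: str,
    config: SelectionConfig | None = None,
) -> EvaluationResult:
    """Cross-validated univariate linear model for the final feature.

    Per fold: ordinary least squares of the label on the single feature,
    validation MAE (s) and Pearson r between predictions and actual labels,
    and the fitted slope.  Aggregates are reported both as the arithmetic
    mean over folds and pooled over all validation predictions.
    """
    config = config or SelectionConfig()
    if feature_name not in table.values.columns:
        raise KeyError(f"feature {feature_name!r} not in the table")
    x = table.values[feature_name].to_numpy(dtype=float)
    y = table.label.to_numpy(dtype=float)
    subjects = np.asarray(table.subject_ids)

    fold_rows, pred_rows = [], []
    for fold, (train_idx, val_idx) in enumerate(_folds(table.values.index, config)):
        if np.std(x[train_idx]) == 0.0:
            raise ValueError(
                f"feature {feature_name!r} has zero variance in fold {fold} training set"
            )
        model = LinearRegression().fit(x[train_idx, None], y[train_idx])
        pred = model.predict(x[val_idx, None])
        mae = float(np.mean(np.abs(pred - y[val_idx])))
        r = float(stats.pearsonr(pred, y[val_idx]).statistic)
        fold_rows.append(
            {"fold": fold, "mae": mae, "pearson_r": r, "slope": float(model.coef_[0])}
        )
        for sid, actual, p in zip(subjects[val_idx], y[val_idx], pred):
            pred_rows.append(
                {"subject_id": sid, "fold": fold, "actual": float(actual),
                 "predicted": float(p)}
            )
    per_fold = pd.DataFrame(fold_rows)
    predictions = pd.DataFrame(pred_rows)
    pooled_err = np.abs(predictions["predicted"] - predictions["actual"])
    pooled_r = float(
        stats.pearsonr(predictions["predicted"], predictions["actual"]).statistic
    )
    return EvaluationResult(
        per_fold=per_fold,
        predictions=predictions,
        mean_mae=float(per_fold["mae"].mean()),
        mean_r=float(per_fold["pearson_r"].mean()),
        pooled_mae=float(pooled_err.mean()),
        pooled_r=pooled_r,
    )


def plot_predictions(result: EvaluationResult, path) -> None:
    """Predicted-vs-actual scatter with the identity line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    actual = result.predictions["actual"]
    predicted = result.predictions["predicted"]
    ax.scatter(actual, predicted, s=18, alpha=0.75)
    lims = [min(actual.min(), predicted.min()) - 1, max(actual.max(), predicted.max()) + 1]
    ax.plot(lims, lims, color="grey", lw=1)
    ax.set_xlabel("Actual TUG (s)")
    ax.set_ylabel("Predicted TUG (s)")
    ax.set_title(
        f"pooled MAE {result.pooled_mae:.2f} s, pooled r {result.pooled_r:.3f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
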