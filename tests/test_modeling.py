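"""Penalized selection, frequency analysis, VIF, model comparison and the
final univariate model."""

import numpy as np
import pandas as pd
import pytest

from pvv.features import FeatureTable
from pvv.modeling import (
    SelectionConfig,
    SelectionError,
    compare_models,
    fit_final_single_feature,
    frequency_analysis,
    lasso_sweep_select,
    run_selection,
    variance_inflation,
)


def _table(n=50, p=120, seed=0, signal_col="f000", slope=-3.0, noise=0.1):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        columns=[f"f{i:03d}" for i in range(p)],
        index=[f"S{i:03d}" for i in range(n)],
    )
    y = 10.0 + slope * X[signal_col] + rng.normal(0, noise, n)
    return FeatureTable(values=X, label=pd.Series(y.to_numpy(), index=X.index))


class TestLassoSweep:
    def test_planted_signal_among_noise_is_recovered(self):
        table = _table(n=48, seed=1)
        _, coefs = lasso_sweep_select(table.values, table.label)
        assert "f000" in coefs.index
        assert len(coefs) <= 3

    def test_overpenalized_grid_raises(self):
        table = _table(n=30, seed=2)
        config = SelectionConfig(alpha_grid=np.array([1e6]))
        with pytest.raises(SelectionError, match="alpha grid"):
            lasso_sweep_select(table.values, table.label, config)

    def test_selection_size_always_in_cap(self):
        for seed in range(5):
            table = _table(n=40, seed=seed, noise=2.0)
            _, coefs = lasso_sweep_select(table.values, table.label)
            assert 1 <= len(coefs) <= 3

    def test_too_few_rows_rejected(self):
        table = _table(n=4)
        with pytest.raises(ValueError, match="training subjects"):
            lasso_sweep_select(table.values, table.label)

    def test_alpha_grid_must_be_decreasing(self):
        with pytest.raises(ValueError, match="decreasing"):
            SelectionConfig(alpha_grid=np.array([1.0, 2.0]))


class TestFrequencyAnalysis:
    def test_counts_and_argmax(self):
        folds = [
            pd.Series({"A": 1.0, "B": 0.5}),
            pd.Series({"A": 0.9}),
            pd.Series({"A": 1.1, "C": 0.2}),
        ]
        freq, final = frequency_analysis(folds)
        assert freq.to_dict() == {"A": 3, "B": 1, "C": 1}
        assert final == "A"

    def test_tie_broken_by_mean_absolute_coefficient(self):
        folds = [pd.Series({"A": 0.4, "B": -0.9, "C": 0.1})]
        _, final = frequency_analysis(folds)
        assert final == "B"

    def test_remaining_tie_broken_lexicographically(self):
        folds = [pd.Series({"B": 0.5, "A": -0.5})]
        _, final = frequency_analysis(folds)
        assert final == "A"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            frequency_analysis([])


class TestVIF:
    def test_orthogonal_features_have_unit_vif(self):
        X = pd.DataFrame(
            {"a": [1, -1, 1, -1, 1, -1], "b": [1, 1, -1, -1, 1, 1]}, dtype=float
        )
        vif = variance_inflation(X)
        assert vif["a"] == pytest.approx(1.0, abs=1e-9)
        assert vif["b"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_column_is_unbounded(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        vif = variance_inflation(X)
        assert np.isinf(vif["a"]) and np.isinf(vif["b"])

    def test_matches_explicit_least_squares(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=200)
        X = pd.DataFrame(
            {f"v{j}": 0.95 * base + np.sqrt(1 - 0.95**2) * rng.normal(size=200)
             for j in range(3)}
        )
        vif = variance_inflation(X)
        for j, name in enumerate(X.columns):
            others = X.drop(columns=name).to_numpy()
            design = np.column_stack([np.ones(len(X)), others])
            target = X[name].to_numpy()
            beta, *_ = np.linalg.lstsq(design, target, rcond=None)
            resid = target - design @ beta
            r2 = 1 - resid.var() / target.var()
            assert vif[name] == pytest.approx(1.0 / (1.0 - r2), abs=1e-8)

    def test_needs_more_rows_than_features(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError, match="rows"):
            variance_inflation(X)

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError, match="2 features"):
            variance_inflation(pd.DataFrame({"a": np.arange(5.0)}))


class TestCompareModels:
    def test_noiseless_linear_label_is_solved_by_linear_family(self):
        table = _table(n=40, seed=4, noise=0.0)
        config = SelectionConfig(seed=4)
        selection = run_selection(table, config)
        result = compare_models(table, selection, config)
        lr = result[(result["model"] == "LR") & (result["fold"] == "mean")]
        assert float(lr["mae"].iloc[0]) < 1e-8

    def test_output_has_four_families_by_folds(self):
        table = _table(n=30, seed=5)
        config = SelectionConfig(seed=5)
        selection = run_selection(table, config)
        result = compare_models(table, selection, config)
        per_fold = result[result["fold"] != "mean"]
        assert len(per_fold) == 4 * config.n_folds
        assert set(result["model"]) == {"LR", "RF", "SVM", "XGB"}

    def test_invariant_to_feature_column_order(self):
        table = _table(n=30, seed=6)
        config = SelectionConfig(seed=6)
        selection = run_selection(table, config)
        a = compare_models(table, selection, config)
        reordered = FeatureTable(
            values=table.values[list(table.values.columns[::-1])], label=table.label
        )
        b = compare_models(reordered, selection, config)
        pd.testing.assert_frame_equal(a, b)

    def test_constant_feature_yields_train_mean_baseline(self):
        """With a zero-variance predictor, OLS predicts the training mean, so
        fold MAE equals the validation labels' deviation around it."""
        from sklearn.model_selection import KFold
        from pvv.modeling import FoldSelection, SelectionReport

        rng = np.random.default_rng(7)
        n = 30
        X = pd.DataFrame(
            {"const": np.ones(n), "other": rng.normal(size=n)},
            index=[f"S{i}" for i in range(n)],
        )
        y = rng.normal(10, 2, n)
        table = FeatureTable(values=X, label=pd.Series(y, index=X.index))
        config = SelectionConfig(seed=7)
        per_fold = [
            FoldSelection(fold=i, alpha=1.0, coefficients=pd.Series({"const": 0.0}),
                          vif=None)
            for i in range(config.n_folds)
        ]
        selection = SelectionReport(
            per_fold=per_fold,
            frequency=pd.Series({"const": config.n_folds}),
            final_feature="const",
        )
        result = compare_models(table, selection, config)
        splits = list(
            KFold(config.n_folds, shuffle=True, random_state=config.seed).split(
                np.arange(n)
            )
        )
        for fold, (train_idx, val_idx) in enumerate(splits):
            expected = np.mean(np.abs(y[val_idx] - y[train_idx].mean()))
            got = result[(result["model"] == "LR") & (result["fold"] == fold)]
            assert float(got["mae"].iloc[0]) == pytest.approx(expected, abs=1e-9)


class TestFinalModel:
    def test_noiseless_link_gives_perfect_fold_metrics(self):
        table = _table(n=40, seed=8, noise=0.0)
        result = fit_final_single_feature(table, "f000", SelectionConfig(seed=8))
        assert (result.per_fold["pearson_r"] > 1 - 1e-9).all()
        assert result.mean_mae < 1e-8

    def test_mean_mae_is_arithmetic_mean_of_folds(self):
        table = _table(n=45, seed=9, noise=1.0)
        result = fit_final_single_feature(table, "f000", SelectionConfig(seed=9))
        assert result.mean_mae == pytest.approx(
            result.per_fold["mae"].mean(), abs=1e-12
        )
        assert result.pooled_mae == pytest.approx(
            np.mean(np.abs(result.predictions["predicted"]
                           - result.predictions["actual"])), abs=1e-12,
        )

    def test_every_subject_validated_exactly_once(self):
        table = _table(n=37, seed=10)
        result = fit_final_single_feature(table, "f000", SelectionConfig(seed=10))
        assert sorted(result.predictions["subject_id"]) == sorted(table.subject_ids)

    def test_negative_link_gives_negative_slopes(self):
        table = _table(n=40, seed=11, slope=-2.0, noise=0.5)
        result = fit_final_single_feature(table, "f000", SelectionConfig(seed=11))
        assert (result.per_fold["slope"] < 0).all()

    def test_zero_variance_feature_rejected(self):
        table = _table(n=30, seed=12)
        table.values["f000"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            fit_final_single_feature(table, "f000", SelectionConfig(seed=12))

    def test_unknown_feature_rejected(self):
        table = _table(n=30, seed=13)
        with pytest.raises(KeyError):
            fit_final_single_feature(table, "nope", SelectionConfig())


def test_run_selection_reports_vif_for_multifeature_folds():
    table = _table(n=50, seed=14, noise=2.0)
    report = run_selection(table, SelectionConfig(seed=14))
    for fs in report.per_fold:
        assert 1 <= len(fs.coefficients) <= 3
        if len(fs.coefficients) >= 2:
            assert fs.vif is not None
            assert set(fs.vif.index) == set(fs.coefficients.index)
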