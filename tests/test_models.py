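"""Stepwise regression, the regularized-track building blocks, and their
statistical contracts (leakage, equivalence to OLS, selection behavior)."""

import numpy as np
import pandas as pd
import pytest

from ppgr_pipeline.models import (
    FittedModel,
    add_polynomial,
    apply_normalization,
    default_grid,
    evaluate,
    fit_regularized,
    grouped_kfold,
    grouped_split,
    normalize_columns,
    spearman_prefilter,
    stepwise_forward,
)


def gaussian_design(n=300, p=6, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    return rng, X


class TestStepwise:
    def test_perfect_predictor_selected_first_with_r_one(self):
        rng, X = gaussian_design()
        y = 2.0 + 3.0 * X["x1"]
        trace, model = stepwise_forward(X, y)
        assert trace.entered[0] == "x1"
        assert trace.steps[0].r == pytest.approx(1.0)
        assert model.coef["x1"] == pytest.approx(3.0)
        assert model.intercept == pytest.approx(2.0)

    def test_largest_marginal_correlation_enters_first(self):
        rng, X = gaussian_design(n=500, seed=3)
        y = 1.0 * X["x2"] + 0.3 * X["x4"] + rng.normal(0, 0.5, len(X))
        trace, _ = stepwise_forward(X, y)
        assert trace.entered[0] == "x2"
        assert "x4" in trace.entered

    def test_r2_trace_monotone_nondecreasing(self):
        rng, X = gaussian_design(n=200, p=10, seed=5)
        y = X.to_numpy() @ rng.normal(size=10) + rng.normal(0, 1, 200)
        trace, _ = stepwise_forward(X, y)
        r2 = [s.r2 for s in trace.steps]
        assert all(b >= a - 1e-12 for a, b in zip(r2[:-1], r2[1:]))

    def test_row_permutation_invariance(self):
        rng, X = gaussian_design(n=150, seed=7)
        y = pd.Series(X["x0"] * 0.8 + rng.normal(0, 1, len(X)))
        t1, _ = stepwise_forward(X, y)
        perm = rng.permutation(len(X))
        t2, _ = stepwise_forward(X.iloc[perm].reset_index(drop=True), y.iloc[perm].to_numpy())
        assert t1.entered == t2.entered
        assert [s.r2 for s in t1.steps] == pytest.approx([s.r2 for s in t2.steps])

    def test_noise_features_not_entered(self):
        rng, X = gaussian_design(n=400, seed=9)
        y = 1.5 * X["x0"] + rng.normal(0, 0.3, len(X))
        trace, _ = stepwise_forward(X, y, alpha_enter=0.01)
        assert trace.entered[0] == "x0"
        assert len(trace.entered) <= 3  # stopping rule keeps pure noise out

    def test_adjusted_r2_formula(self):
        rng, X = gaussian_design(n=100, seed=11)
        y = X["x0"] + rng.normal(0, 1, 100)
        trace, _ = stepwise_forward(X, y)
        s = trace.steps[-1]
        p = len(trace.steps)
        n = 100
        assert s.adj_r2 == pytest.approx(1 - (1 - s.r2) * (n - 1) / (n - p - 1))


class TestPrefilter:
    def test_identical_feature_retained(self):
        rng, X = gaussian_design()
        y = X["x3"].to_numpy()
        assert "x3" in spearman_prefilter(X, y)

    def test_independent_feature_excluded_at_large_n(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame({"signal": rng.normal(size=1000), "junk": rng.normal(size=1000)})
        y = X["signal"].to_numpy() + rng.normal(0, 0.5, 1000)
        kept = spearman_prefilter(X, y, threshold=0.1)
        assert kept == ["signal"]

    def test_zero_threshold_keeps_all_nonconstant(self):
        rng, X = gaussian_design()
        X["const"] = 1.0
        y = rng.normal(size=len(X))
        kept = spearman_prefilter(X, y, threshold=0.0)
        assert "const" not in kept
        assert set(kept) == {f"x{i}" for i in range(6)}


class TestNormalization:
    def test_hand_computed_example(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        Xn, constants, dropped = normalize_columns(X)
        assert constants["a"] == (2.0, pytest.approx(np.sqrt(2)))
        assert Xn["a"].to_numpy() == pytest.approx([-1 / np.sqrt(2), 0, 1 / np.sqrt(2)])
        assert dropped == []

    def test_centered_unit_norm_fixed_point(self):
        x = np.array([-1 / np.sqrt(2), 0, 1 / np.sqrt(2)])
        Xn, _, _ = normalize_columns(pd.DataFrame({"a": x}))
        assert Xn["a"].to_numpy() == pytest.approx(x)

    def test_constant_column_dropped_with_warning(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [4.0, 4.0, 4.0]})
        with pytest.warns(UserWarning, match="constant"):
            Xn, constants, dropped = normalize_columns(X)
        assert dropped == ["c"] and "c" not in Xn.columns

    def test_constants_reapplied_verbatim(self):
        rng, X = gaussian_design(n=50)
        Xn, constants, _ = normalize_columns(X)
        Xnew = apply_normalization(X.iloc[:10] * 1.0, constants)
        pd.testing.assert_frame_equal(Xnew, Xn.iloc[:10])


class TestGroupedSplits:
    def test_patient_sets_disjoint_and_fraction_respected(self):
        groups = np.repeat([f"p{i}" for i in range(10)], 10)
        tr, te = grouped_split(groups, fraction=0.7, seed=0)
        assert set(groups[tr]) & set(groups[te]) == set()
        assert len(tr) == 70 and len(te) == 30

    def test_split_deterministic_per_seed(self):
        groups = np.repeat([f"p{i}" for i in range(12)], 5)
        a = grouped_split(groups, seed=4)
        b = grouped_split(groups, seed=4)
        c = grouped_split(groups, seed=5)
        assert np.array_equal(a[0], b[0])
        assert not np.array_equal(a[0], c[0])

    def test_single_patient_errors(self):
        with pytest.raises(ValueError):
            grouped_split(np.array(["p0"] * 20))

    def test_kfold_partitions_patients(self):
        groups = np.repeat([f"p{i}" for i in range(20)], 3)
        folds = grouped_kfold(groups, k=10, seed=1)
        assert len(folds) == 10
        val_groups = [set(groups[va]) for _, va in folds]
        for i, a in enumerate(val_groups):
            for b in val_groups[i + 1:]:
                assert a & b == set()
        assert set().union(*val_groups) == set(groups)
        for tr, va in folds:
            assert set(groups[tr]) & set(groups[va]) == set()

    def test_kfold_requires_enough_patients(self):
        with pytest.raises(ValueError):
            grouped_kfold(np.array(["a", "a", "b"]), k=3)


class TestFitRegularized:
    def test_omp_recovers_single_planted_feature(self):
        rng = np.random.default_rng(17)
        n = 1500
        X = pd.DataFrame(
            {
                "carbo": rng.normal(45, 20, n),
                **{f"junk{i}": rng.normal(size=n) for i in range(8)},
            }
        )
        groups = np.repeat([f"p{i}" for i in range(30)], n // 30)
        y = 0.01 * X["carbo"].to_numpy() + rng.normal(0, 0.05, n)
        model = fit_regularized(X, y, groups, method="omp", k=10, seed=0)
        assert model.columns == ["carbo"]
        coef = model.coef_original_scale()["carbo"]
        assert coef == pytest.approx(0.01, abs=3 * 0.05 / (20 * np.sqrt(n)))

    def test_single_point_grid_equals_direct_fit(self):
        rng = np.random.default_rng(19)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        groups = np.repeat([f"p{i}" for i in range(10)], 20)
        y = X["a"].to_numpy() + rng.normal(0, 0.2, n)
        m = fit_regularized(X, y, groups, method="omp", grid=[1], k=5, seed=0)
        assert m.hyperparameters["param"] == 1
        assert m.columns == ["a"]

    def test_empty_grid_errors(self):
        rng, X = gaussian_design(n=60)
        groups = np.repeat(list("abcdef"), 10)
        with pytest.raises(ValueError, match="grid"):
            fit_regularized(X, rng.normal(size=60), groups, method="omp", grid=[], k=3)

    def test_cv_score_of_chosen_point_is_maximal(self):
        # contract: the grid point the fit reports beats a worse alternative
        rng = np.random.default_rng(23)
        n = 400
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"x{i}" for i in range(6)])
        groups = np.repeat([f"p{i}" for i in range(20)], 20)
        y = X["x0"].to_numpy() * 2 + X["x1"].to_numpy() + rng.normal(0, 0.5, n)
        best = fit_regularized(X, y, groups, method="omp", grid=[1, 2, 3, 4], k=5, seed=1)
        only1 = fit_regularized(X, y, groups, method="omp", grid=[1], k=5, seed=1)
        assert best.cv_score >= only1.cv_score - 1e-12

    @pytest.mark.parametrize("method", ["lasso", "ridge", "elastic_net", "lars_lasso"])
    def test_penalized_methods_run_and_predict(self, method):
        rng = np.random.default_rng(29)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"x{i}" for i in range(5)])
        groups = np.repeat([f"p{i}" for i in range(10)], 20)
        y = X["x0"].to_numpy() + rng.normal(0, 0.3, n)
        grid = default_grid(method)[:6]
        m = fit_regularized(X, y, groups, method=method, grid=grid, k=5, seed=2)
        rep = evaluate(m, X, y)
        assert rep.pearson_r > 0.8

    def test_serialization_roundtrip(self):
        rng = np.random.default_rng(31)
        n = 120
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        groups = np.repeat([f"p{i}" for i in range(6)], 20)
        y = X["a"].to_numpy() + rng.normal(0, 0.1, n)
        m = fit_regularized(X, y, groups, method="omp", grid=[1, 2], k=3, seed=0)
        m2 = FittedModel.from_text(m.to_text())
        assert m2.to_text() == m.to_text()
        assert m2.predict(X) == pytest.approx(m.predict(X))


class TestPolynomial:
    def test_three_meal_features_add_six_columns(self, small_result):
        base = small_result.design
        import dataclasses

        trimmed = dataclasses.replace(
            base,
            meal_cols=["carbo", "prot", "fat"],
        )
        out = add_polynomial(trimmed)
        new = set(out.feature_cols) - set(base.feature_cols)
        assert new == {
            "carbo^2", "prot^2", "fat^2",
            "carbo × prot", "carbo × fat", "prot × fat",
        }

    def test_square_column_is_elementwise_square(self, small_result):
        out = add_polynomial(small_result.design)
        np.testing.assert_allclose(
            out.frame["carbo^2"].to_numpy(),
            small_result.design.frame["carbo"].to_numpy() ** 2,
        )

    def test_unknown_meal_feature_errors(self, small_result):
        with pytest.raises(ValueError):
            add_polynomial(small_result.design, meal_features=["nope"])


class TestEvaluate:
    def test_perfect_predictions(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        m = FittedModel("y", "with_gigl", "omp", ["a"], {"a": 2.0}, 0.0, None, {})
        rep = evaluate(m, X, 2.0 * X["a"].to_numpy())
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.mae == pytest.approx(0.0)
        assert rep.r2 == pytest.approx(1.0)

    def test_constant_shift_keeps_r_one_with_mae_offset(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        m = FittedModel("y", "with_gigl", "omp", ["a"], {"a": 2.0}, 0.5, None, {})
        rep = evaluate(m, X, 2.0 * X["a"].to_numpy())
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.mae == pytest.approx(0.5)

    def test_zero_variance_predictions_report_nan_r(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        m = FittedModel("y", "with_gigl", "omp", [], {}, 1.0, None, {})
        rep = evaluate(m, X, np.array([1.0, 2.0, 3.0]))
        assert np.isnan(rep.pearson_r)

    def test_error_fraction_threshold(self):
        X = pd.DataFrame({"a": [0.0, 0.0, 0.0, 0.0]})
        m = FittedModel("y", "with_gigl", "omp", [], {}, 0.0, None, {})
        y = np.array([0.5, 1.5, -2.0, 0.1])
        rep = evaluate(m, X, y, abs_error_threshold=1.0)
        assert rep.frac_abs_error_gt_threshold == pytest.approx(0.5)
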