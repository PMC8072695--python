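"""Closed-form ridge, scaling, stratified folds and cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from nutrigap.cohort import INTAKE_VARS
from nutrigap.ridge import (
    DesignMatrix,
    SingularSystemError,
    ZeroVarianceError,
    cross_validate,
    fit_all_outcomes,
    fit_ridge,
    lasso_solve,
    r2_table,
    ridge_solve,
    standard_scale_fit,
    stratified_folds,
)
from nutrigap.screen import screen_cohort
from nutrigap.simulate import GeneratorConfig, generate_cohort


def _random_problem(rng, n, p):
    X = rng.normal(size=(n, p)) * rng.uniform(0.5, 3.0, size=p)
    y = rng.normal(size=n)
    scaler = standard_scale_fit(X, y)
    return scaler.apply(X, y)


class TestScaling:
    def test_fit_apply_standardises(self, rng):
        X = rng.normal(5.0, 3.0, size=(40, 4))
        y = rng.normal(2.0, 1.0, size=40)
        scaler = standard_scale_fit(X, y)
        Xs, ys = scaler.apply(X, y)
        assert np.all(np.abs(Xs.mean(axis=0)) < 1e-12)
        assert np.allclose(Xs.std(axis=0), 1.0, atol=1e-12)
        assert abs(ys.mean()) < 1e-12

    def test_constant_column_raises_named_error(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 4.2
        with pytest.raises(ZeroVarianceError, match="colB"):
            standard_scale_fit(X, rng.normal(size=20),
                               column_names=("colA", "colB", "colC"))

    def test_scaler_fitted_on_one_split_does_not_centre_another(self, rng):
        A = rng.normal(0.0, 1.0, size=(50, 3))
        B = A + 2.5  # shifted split
        scaler = standard_scale_fit(A, np.zeros(50))
        Bs = scaler.apply(B)
        assert np.all(np.abs(Bs.mean(axis=0)) > 1.0)  # no leakage


class TestRidgeSolve:
    def test_alpha_zero_equals_ols(self, rng):
        Xs, ys = _random_problem(rng, 30, 5)
        beta = ridge_solve(Xs, ys, 0.0)
        beta_ols, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        assert np.allclose(beta, beta_ols, atol=1e-10)

    def test_huge_alpha_shrinks_to_zero(self, rng):
        Xs, ys = _random_problem(rng, 30, 5)
        beta = ridge_solve(Xs, ys, 1e9)
        assert np.max(np.abs(beta)) < 1e-6

    def test_matches_brute_force_objective_minimiser(self, rng):
        Xs, ys = _random_problem(rng, 12, 4)
        alpha = 2.5
        beta = ridge_solve(Xs, ys, alpha)

        def objective(b):
            r = ys - Xs @ b
            return r @ r + alpha * b @ b

        res = minimize(objective, np.zeros(4), method="BFGS",
                       options={"gtol": 1e-12})
        assert np.allclose(beta, res.x, atol=1e-6)
        # first-order optimality of the closed form
        grad = -2 * Xs.T @ (ys - Xs @ beta) + 2 * alpha * beta
        assert np.max(np.abs(grad)) < 1e-8

    def test_matches_sklearn_ridge(self, rng):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        Xs, ys = _random_problem(rng, 40, 6)
        for alpha in (0.1, 1.0, 50.0):
            ours = ridge_solve(Xs, ys, alpha)
            theirs = sklearn_linear.Ridge(
                alpha=alpha, fit_intercept=False).fit(Xs, ys).coef_
            assert np.allclose(ours, theirs, atol=1e-8)

    def test_collinear_at_alpha_zero_raises(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 2] = X[:, 0] + X[:, 1]
        Xs = X - X.mean(axis=0)
        with pytest.raises(SingularSystemError, match="alpha"):
            ridge_solve(Xs, rng.normal(size=20), 0.0)

    def test_row_duplication_with_doubled_alpha_is_invariant(self, rng):
        """Stacking every row twice doubles X'X and X'y, so the solution
        at penalty 2*alpha equals the original solution at alpha."""
        Xs, ys = _random_problem(rng, 25, 4)
        X2 = np.vstack([Xs, Xs])
        y2 = np.concatenate([ys, ys])
        assert np.allclose(
            ridge_solve(Xs, ys, 3.0), ridge_solve(X2, y2, 6.0), atol=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_shrinkage(self, seed):
        rng = np.random.default_rng(seed)
        Xs, ys = _random_problem(rng, 25, 5)
        norms = [np.linalg.norm(ridge_solve(Xs, ys, a))
                 for a in (0.0, 0.5, 5.0, 50.0, 500.0)]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_lasso_baseline_matches_sklearn(self, rng):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        Xs, ys = _random_problem(rng, 40, 5)
        n = len(ys)
        alpha = 8.0
        ours = lasso_solve(Xs, ys, alpha)
        # sklearn minimises (1/2n)||y-Xb||^2 + a||b||_1
        theirs = sklearn_linear.Lasso(
            alpha=alpha / (2 * n), fit_intercept=False).fit(Xs, ys).coef_
        assert np.allclose(ours, theirs, atol=1e-6)


class TestStratifiedFolds:
    def test_exact_divisibility_one_per_centre_per_fold(self):
        labels = np.repeat(["a", "b", "c", "d"], 5)
        folds = stratified_folds(labels, k=5, seed=3)
        for f in range(5):
            centres = labels[folds == f]
            assert sorted(centres) == ["a", "b", "c", "d"]

    def test_small_centre_spreads_over_distinct_folds(self):
        labels = ["big"] * 20 + ["tiny"] * 3
        folds = np.asarray(stratified_folds(labels, k=5, seed=0))
        tiny = folds[20:]
        assert len(set(tiny)) == 3

    def test_study_sized_counts_differ_by_at_most_one(self):
        rng = np.random.default_rng(1)
        labels = rng.choice(["bo", "cf", "ka", "le"], size=157,
                            p=[0.3, 0.25, 0.25, 0.2])
        folds = stratified_folds(labels, k=5, seed=9)
        for centre in np.unique(labels):
            counts = np.bincount(folds[labels == centre], minlength=5)
            assert counts.max() - counts.min() <= 1
        total = np.bincount(folds, minlength=5)
        assert total.max() - total.min() <= 1

    def test_deterministic_given_seed(self):
        labels = ["a", "b"] * 20
        f1 = stratified_folds(labels, k=5, seed=4)
        f2 = stratified_folds(labels, k=5, seed=4)
        f3 = stratified_folds(labels, k=5, seed=5)
        assert np.array_equal(f1, f2)
        assert not np.array_equal(f1, f3)

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError):
            stratified_folds(["a", "b"], k=5)


def _design(rng, n=100, noise=0.0, beta=None, p=6):
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = np.linspace(1.0, 0.2, p)
    y = 2.0 + X @ beta + noise * rng.normal(size=n)
    centres = np.tile(["a", "b", "c", "d"], n // 4 + 1)[:n]
    return DesignMatrix(X=X, y=y, centre_labels=centres,
                        column_names=tuple(f"x{j}" for j in range(p)),
                        outcome_name="y")


class TestCrossValidate:
    def test_noise_free_linear_outcome_recovers_r2_one(self, rng):
        rep = cross_validate(_design(rng, noise=0.0), seed=0)
        assert rep.r2_mean >= 0.999
        assert rep.alpha_selected <= 1.0

    def test_every_subject_in_exactly_one_test_fold(self, rng):
        rep = cross_validate(_design(rng), seed=0)
        all_idx = np.concatenate(rep.fold_test_indices)
        assert sorted(all_idx) == list(range(100))

    def test_r2_mean_is_arithmetic_mean_of_folds(self, rng):
        rep = cross_validate(_design(rng, noise=1.0), seed=0)
        assert rep.r2_mean == pytest.approx(np.mean(rep.fold_r2))
        assert len(rep.fold_r2) == 5

    def test_pure_noise_outcome_stays_near_null(self):
        r2s = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            dm = _design(rng, n=160, p=10, beta=np.zeros(10), noise=1.0)
            r2s.append(cross_validate(dm, seed=seed).r2_mean)
        assert np.mean(r2s) < 0.15

    def test_permuting_y_destroys_fit(self, rng):
        dm = _design(rng, n=160, noise=0.5)
        fitted = cross_validate(dm, seed=1)
        assert fitted.r2_mean > 0.7
        y_perm = np.random.default_rng(0).permutation(dm.y)
        dm_perm = DesignMatrix(X=dm.X, y=y_perm,
                               centre_labels=dm.centre_labels,
                               column_names=dm.column_names,
                               outcome_name="perm")
        assert cross_validate(dm_perm, seed=1).r2_mean < 0.15

    def test_determinism(self, rng):
        dm = _design(rng, noise=1.0)
        a = cross_validate(dm, seed=6)
        b = cross_validate(dm, seed=6)
        assert a.alpha_selected == b.alpha_selected
        assert np.array_equal(a.folds, b.folds)
        assert np.allclose(a.fit.beta, b.fit.beta)

    def test_tiny_fold_raises(self, rng):
        dm = _design(rng, n=8)
        with pytest.raises(ValueError, match="undefined"):
            cross_validate(dm, k=5, seed=0)

    def test_empty_alpha_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_validate(_design(rng), alpha_grid=[], seed=0)


class TestFitAllOutcomes:
    def test_output_shape_is_eleven_by_two(self, study_cohort):
        retained, _, _ = screen_cohort(study_cohort.records)
        results = fit_all_outcomes(retained, seed=0)
        table = r2_table(results)
        assert table.shape[0] == 11
        assert {"female_r2", "male_r2"} <= set(table.columns)
        assert table[["female_r2", "male_r2"]].notna().all().all()

    def test_same_folds_reused_across_outcomes_within_gender(self, study_cohort):
        retained, _, _ = screen_cohort(study_cohort.records)
        results = fit_all_outcomes(retained, seed=0)
        folds_bmi = results["male"]["bmi"].folds
        folds_tg = results["male"]["tg"].folds
        assert np.array_equal(folds_bmi, folds_tg)

    def test_signal_planted_only_in_males_shows_up_only_there(self):
        cfg = GeneratorConfig(n_female=90, n_male=90, seed=21,
                              misreporter_fraction=0.0)
        # erase the female BMI signal entirely (pure noise outcome)
        cfg.true_beta["female"]["bmi"] = np.zeros(len(INTAKE_VARS))
        cohort = generate_cohort(cfg)
        results = fit_all_outcomes(cohort.records, seed=2)
        assert results["male"]["bmi"].r2_mean > 0.5
        assert results["female"]["bmi"].r2_mean < 0.25
        assert (results["male"]["bmi"].r2_mean
                - results["female"]["bmi"].r2_mean) > 0.3
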