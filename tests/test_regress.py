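"""Constrained splitting, metrics, grid search, and the repeated-evaluation protocol."""

import numpy as np
import pandas as pd
import pytest

from ramdfp.featurize import FeatureMatrix, minmax_normalize
from ramdfp.regress import (
    SplitConstraints,
    _ridge_cv_mae,
    _shuffle_folds,
    coefficient_summary,
    fit_predict,
    grid_search,
    mae,
    q2f3,
    repeated_evaluation,
    split_train_test,
)
from ramdfp.synthetic import gen_compound_set


class TestMetrics:
    def test_mae_closed_forms(self):
        assert mae([1, 2, 3], [1, 2, 3]) == 0.0
        assert mae([1.5, 2.5], [1.0, 2.0]) == pytest.approx(0.5)
        v = np.array([0.3, -0.2, 0.7, 0.1])
        assert mae(v, np.zeros(4)) == pytest.approx(np.abs(v).sum() / 4)
        with pytest.raises(ValueError):
            mae([1], [1, 2])

    def test_q2f3_perfect_is_one(self):
        assert q2f3([1.0, 2.0], [1.0, 2.0], [0.0, 2.0]) == pytest.approx(1.0)

    def test_q2f3_hand_example(self):
        """Train {0,2}, test obs {1}, pred {0.5}: 1 - (0.25/1)/1 = 0.75."""
        assert q2f3([0.5], [1.0], [0.0, 2.0]) == pytest.approx(0.75)

    def test_q2f3_zero_training_variance(self):
        with pytest.raises(ValueError):
            q2f3([1.0], [1.0], [2.0, 2.0])

    def test_dummy_q2f3_near_zero_for_exchangeable_labels(self, rng):
        """Train-mean predictions give mean Q2F3 ~ 0 over many random splits.

        The null value carries a finite-sample bias of order -4/n_train, so
        the identity is measured on a sample large enough for the bias to
        be negligible against the +-0.05 band.
        """
        n, n_te = 400, 80
        vals = []
        for _ in range(500):
            y = rng.normal(size=n)
            perm = rng.permutation(n)
            te, tr = perm[:n_te], perm[n_te:]
            vals.append(q2f3(np.full(n_te, y[tr].mean()), y[te], y[tr]))
        assert abs(np.mean(vals)) < 0.05

    def test_dummy_test_mae_closed_form(self, planted_matrix):
        """Dummy test MAE equals mean |y_test - mean(y_train)|."""
        matrix, _ = planted_matrix
        tr, te = split_train_test(matrix.compound_ids, seed=3)
        ytr = matrix.labels.loc[tr].to_numpy()
        yte = matrix.labels.loc[te].to_numpy()
        pred, _ = fit_predict("Dummy", np.zeros((len(tr), 1)), ytr,
                              np.zeros((len(te), 1)))
        assert mae(pred, yte) == pytest.approx(
            np.abs(yte - ytr.mean()).mean())


class TestSplits:
    def test_study_sized_constrained_split(self, planted_matrix):
        """94 annotated compounds: test of 19 with 2 outliers and >= 9 indazoles."""
        matrix, _ = planted_matrix
        c = SplitConstraints.from_annotations(matrix.annotations)
        train, test = split_train_test(matrix.compound_ids, c, seed=0)
        assert len(test) == 19
        assert len(set(c.outlier_pool) & set(test)) == 2
        assert len(set(c.indazole_pool) & set(test)) >= 9
        assert sorted(train + test) == sorted(matrix.compound_ids)
        assert not set(train) & set(test)

    def test_no_pools_plain_random_split(self):
        ids = [f"c{i}" for i in range(40)]
        train, test = split_train_test(ids, None, seed=1)
        assert len(test) == 8
        assert sorted(train + test) == sorted(ids)

    @pytest.mark.parametrize("seed", range(0, 1000, 5))
    def test_constraints_hold_across_seeds(self, planted_matrix, seed):
        matrix, _ = planted_matrix
        c = SplitConstraints.from_annotations(matrix.annotations)
        _, test = split_train_test(matrix.compound_ids, c, seed=seed)
        assert len(test) == 19
        assert len(set(c.outlier_pool) & set(test)) >= 2
        assert len(set(c.indazole_pool) & set(test)) >= 9

    def test_deterministic_under_seed(self, planted_matrix):
        matrix, _ = planted_matrix
        c = SplitConstraints.from_annotations(matrix.annotations)
        s1 = split_train_test(matrix.compound_ids, c, seed=17)
        s2 = split_train_test(matrix.compound_ids, c, seed=17)
        assert s1 == s2

    def test_pool_too_small_errors(self):
        ids = [f"c{i}" for i in range(20)]
        c = SplitConstraints(outlier_pool=("c0",), n_outlier_in_test=2)
        with pytest.raises(ValueError, match="pool"):
            split_train_test(ids, c, seed=0)


class TestGridSearch:
    def test_single_point_grid(self, rng):
        X = rng.random((20, 3))
        y = rng.normal(size=20)
        params = grid_search("LR", X, y, grids={"LR": {"alpha": [0.7]}})
        assert params == {"alpha": 0.7}

    def test_svd_path_equals_sklearn(self, rng):
        """The SVD ridge CV is numerically identical to per-fold sklearn fits."""
        from sklearn.linear_model import Ridge

        X = rng.random((50, 12))
        y = X @ rng.normal(size=12) + rng.normal(0, 0.2, 50)
        alphas = np.logspace(-3, 3, 13)
        folds = _shuffle_folds(50, 10, 0.2, 3)
        mine = _ridge_cv_mae(X, y, alphas, folds)
        ref = np.array([
            np.mean([np.abs(Ridge(alpha=a).fit(X[tr], y[tr])
                            .predict(X[va]) - y[va]).mean()
                     for tr, va in folds]) for a in alphas])
        assert np.allclose(mine, ref, atol=1e-10)

    def test_ridge_choice_matches_brute_force(self, rng):
        """Selected strength equals the exhaustive-evaluation optimum."""
        X = rng.random((60, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.3, 60)
        grid = {"LR": {"alpha": np.logspace(-3, 3, 13)}}
        params = grid_search("LR", X, y, grids=grid, seed=5)
        folds = _shuffle_folds(60, 10, 0.2, 5)
        errs = _ridge_cv_mae(X, y, grid["LR"]["alpha"], folds)
        assert params["alpha"] == pytest.approx(
            grid["LR"]["alpha"][int(np.argmin(errs))])

    def test_svr_beats_median_grid_point(self, rng):
        X = rng.random((60, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.2, 60)
        Xte = rng.random((40, 8))
        yte = Xte @ np.zeros(8)  # placeholder; recompute below
        w = np.linalg.lstsq(X, y, rcond=None)[0]
        yte = Xte @ w
        params = grid_search("SVR", X, y, seed=2)
        best, _ = fit_predict("SVR", X, y, Xte, params)
        med = {"C": 10.0, "epsilon": 0.1, "gamma": 0.1}
        base, _ = fit_predict("SVR", X, y, Xte, med)
        assert mae(best, yte) <= mae(base, yte) + 0.05

    def test_empty_grid_errors(self, rng):
        with pytest.raises(ValueError, match="grid"):
            grid_search("SVR", rng.random((20, 2)), rng.normal(size=20),
                        grids={"SVR": {"C": [], "epsilon": [], "gamma": []}})

    def test_too_small_training_set(self, rng):
        with pytest.raises(ValueError, match="small"):
            grid_search("LR", rng.random((5, 2)), rng.normal(size=5))


class TestFitPredict:
    def test_dummy_predicts_train_mean(self):
        pred, _ = fit_predict("Dummy", np.zeros((2, 1)), [0.0, 2.0],
                              np.zeros((3, 1)))
        assert np.allclose(pred, 1.0)

    def test_lr_recovers_planted_weights_noiseless(self, rng):
        X = rng.random((40, 5))
        w = rng.normal(size=5)
        y = X @ w + 2.0
        pred, coefs = fit_predict("LR", X, y, X, {"alpha": 1e-10})
        assert np.allclose(coefs, w, atol=1e-5)
        assert np.allclose(pred, y, atol=1e-6)

    def test_svr_train_error_within_epsilon(self, rng):
        X = np.tile(rng.random(4), (30, 1))
        y = np.full(30, 0.5)
        pred, _ = fit_predict("SVR", X, y, X,
                              {"C": 10.0, "epsilon": 0.1, "gamma": 0.5})
        assert mae(pred, y) <= 0.1 + 1e-8


class TestRepeatedEvaluation:
    def test_single_round_structure(self, planted_matrix):
        matrix, _ = planted_matrix
        res = repeated_evaluation(minmax_normalize(matrix), n_rounds=1,
                                  seed=0, models=("LR", "Dummy"))
        assert not res.failures
        subsets = {(r.model, r.subset) for r in res.rounds}
        assert subsets == {(m, s) for m in ("LR", "Dummy")
                           for s in ("train", "validation", "test")}

    def test_lr_beats_dummy_on_planted_data(self, planted_matrix):
        matrix, _ = planted_matrix
        res = repeated_evaluation(minmax_normalize(matrix), n_rounds=20,
                                  seed=1, models=("LR", "Dummy"))
        assert (res.scores("LR", "test", "mae").mean()
                < res.scores("Dummy", "test", "mae").mean())

    def test_permuted_labels_q2f3_near_zero(self, planted_matrix, rng):
        """With labels shuffled, no model does better than the null hypothesis."""
        matrix, _ = planted_matrix
        norm = minmax_normalize(matrix)
        shuffled = FeatureMatrix(
            norm.values,
            pd.Series(rng.permutation(norm.labels.to_numpy()),
                      index=norm.values.index),
            norm.annotations)
        res = repeated_evaluation(shuffled, n_rounds=30, seed=2,
                                  models=("LR", "Dummy"))
        for model in ("LR", "Dummy"):
            assert abs(res.scores(model, "test", "q2f3").mean()) < 0.25

    def test_tau_predictions_evaluated_on_same_test_sets(self, planted_matrix):
        matrix, _ = planted_matrix
        norm = minmax_normalize(matrix)
        tau_pred = norm.labels + 0.3  # constant offset -> MAE 0.3 each round
        res = repeated_evaluation(norm, n_rounds=3, seed=4, models=("Dummy",),
                                  tau_predictions=tau_pred)
        scores = res.scores("tauRAMD", "test", "mae")
        assert np.allclose(scores, 0.3)

    def test_round_failures_recorded_not_swallowed(self, planted_matrix):
        matrix, _ = planted_matrix
        bad = SplitConstraints(outlier_pool=("nope",), n_outlier_in_test=2)
        with pytest.raises(RuntimeError, match="outlier pool"):
            repeated_evaluation(minmax_normalize(matrix), constraints=bad,
                                n_rounds=2, seed=0, models=("Dummy",))


class TestCoefficientSummary:
    def test_single_round_identity(self, planted_matrix):
        matrix, _ = planted_matrix
        res = repeated_evaluation(minmax_normalize(matrix), n_rounds=1,
                                  seed=0, models=("LR",))
        summary = coefficient_summary(res)
        coefs = [r.coefficients for r in res.rounds
                 if r.coefficients is not None][0]
        top = summary.iloc[0]
        assert abs(top["coef_mean"]) == pytest.approx(np.abs(coefs).max())

    def test_symmetric_rounds_cancel(self):
        from ramdfp.regress import EvaluationResult, RoundResult

        c = np.array([1.0, -2.0])
        res = EvaluationResult(
            rounds=[RoundResult(0, "LR", "test", 0.1, 0.5, {}, c),
                    RoundResult(1, "LR", "test", 0.1, 0.5, {}, -c)],
            feature_names=["f1", "f2"])
        summary = coefficient_summary(res)
        assert np.allclose(summary["coef_mean"], 0.0)

    def test_dominant_planted_feature_ranks_first(self, rng):
        X = rng.random((60, 6))
        w = np.array([0.0, 0.0, 3.0, 0.0, 0.0, 0.0])
        y = X @ w + rng.normal(0, 0.1, 60)
        ids = [f"c{i}" for i in range(60)]
        m = FeatureMatrix(
            pd.DataFrame(X, index=ids,
                         columns=[f"X{i + 1}-HB" for i in range(6)]),
            pd.Series(y, index=ids))
        res = repeated_evaluation(m, n_rounds=5, seed=0, models=("LR",))
        summary = coefficient_summary(res)
        assert summary.iloc[0]["feature"] == "X3-HB"
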