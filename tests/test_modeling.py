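"""Confound regression, ridge-family predictors, nested CV, training arms."""

import dataclasses

import numpy as np
import pytest

from fairconn.modeling import (
    KernelModel,
    abcd_split_folds,
    apply_confound_model,
    correlation_kernel,
    default_lambda_grid,
    fit_confound_model,
    fit_krr,
    fit_linear_ridge,
    nested_cv_select_lambda,
    predict_krr,
    predict_linear_ridge,
    subsample_training_population,
)
from fairconn.synthetic import SyntheticConfig, generate_dataset


class TestConfoundModel:
    def test_exact_linear_relation_recovered(self, rng):
        age = rng.normal(size=30)
        y = 2.0 * age
        fc = rng.normal(size=(30, 5))
        model = fit_confound_model(y, fc, age[:, None], ["age"])
        assert model.y_coef[1] == pytest.approx(2.0, abs=1e-10)
        resid, _ = apply_confound_model(model, y, fc, age[:, None])
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_matches_normal_equation_oracle(self, rng):
        C = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        fc = rng.normal(size=(40, 6))
        model = fit_confound_model(y, fc, C)
        X = np.column_stack([np.ones(40), C])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(model.y_coef, oracle, atol=1e-8)
        oracle_fc = np.linalg.solve(X.T @ X, X.T @ fc)
        assert np.allclose(model.fc_coef, oracle_fc, atol=1e-8)

    def test_training_residuals_orthogonal_to_confounds(self, rng):
        C = rng.normal(size=(50, 2))
        y = C @ [1.0, -0.5] + rng.normal(size=50)
        fc = rng.normal(size=(50, 4))
        model = fit_confound_model(y, fc, C)
        resid, _ = apply_confound_model(model, y, fc, C)
        for j in range(2):
            assert abs(np.corrcoef(resid, C[:, j])[0, 1]) < 1e-10

    def test_collinear_columns_named(self, rng):
        age = rng.normal(size=20)
        C = np.column_stack([age, 2 * age])
        with pytest.raises(ValueError, match="collinear"):
            fit_confound_model(rng.normal(size=20), rng.normal(size=(20, 3)),
                               C, ["age", "age_twice"])

    def test_test_subject_at_training_means(self, rng):
        C = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        fc = rng.normal(size=(30, 4))
        model = fit_confound_model(y, fc, C)
        y0 = np.array([1.5])
        mean_row = C.mean(axis=0, keepdims=True)
        resid, _ = apply_confound_model(model, y0, fc[:1], mean_row)
        expected = 1.5 - (model.y_coef[0] + mean_row[0] @ model.y_coef[1:])
        assert resid[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_coefficient_model_is_identity(self, rng):
        from fairconn.modeling import ConfoundModel

        model = ConfoundModel(
            names=["c0"], y_coef=np.zeros(2), fc_coef=np.zeros((2, 3))
        )
        y = rng.normal(size=5)
        fc = rng.normal(size=(5, 3))
        ry, rfc = apply_confound_model(model, y, fc, rng.normal(size=(5, 1)))
        assert np.array_equal(ry, y)
        assert np.array_equal(rfc, fc)


class TestCorrelationKernel:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=(1, 10))
        assert correlation_kernel(x, x)[0, 0] == pytest.approx(1.0)

    def test_orthogonal_rows_zero(self):
        a = np.array([[1.0, -1.0, 1.0, -1.0]])
        b = np.array([[1.0, 1.0, -1.0, -1.0]])
        assert correlation_kernel(a, b)[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pairwise_oracle(self, rng):
        a = rng.normal(size=(5, 10))
        b = rng.normal(size=(4, 10))
        K = correlation_kernel(a, b)
        for i in range(5):
            for j in range(4):
                assert K[i, j] == pytest.approx(
                    np.corrcoef(a[i], b[j])[0, 1], abs=1e-12
                )

    def test_zero_variance_row_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_kernel(np.ones((1, 5)), rng.normal(size=(2, 5)))


class TestRidgeSolvers:
    def test_identity_kernel_solution(self):
        y = np.array([2.0, -4.0, 6.0])
        assert np.allclose(fit_krr(np.eye(3), y, 1.0), y / 2)

    def test_large_lambda_shrinks_to_zero(self, rng):
        K = correlation_kernel(rng.normal(size=(10, 20)), rng.normal(size=(10, 20)))
        K = (K + K.T) / 2
        y = rng.normal(size=10)
        alpha = fit_krr(K, y, 1e8)
        assert np.allclose(alpha, y / 1e8, atol=1e-9)
        model = KernelModel(lam=1e8, dual_coef=alpha,
                            training_fc=np.zeros((10, 2)), training_y=y)
        assert np.abs(predict_krr(model, K)).max() < 1e-6

    def test_matches_explicit_inverse(self, rng):
        X = rng.normal(size=(15, 30))
        K = correlation_kernel(X, X)
        y = rng.normal(size=15)
        lam = 0.37
        oracle = np.linalg.inv(K + lam * np.eye(15)) @ y
        assert np.allclose(fit_krr(K, y, lam), oracle, atol=1e-8)

    def test_predictions_are_kernel_weighted_averages(self, rng):
        X = rng.normal(size=(8, 12))
        y = rng.normal(size=8)
        alpha = fit_krr(correlation_kernel(X, X), y, 0.5)
        model = KernelModel(lam=0.5, dual_coef=alpha, training_fc=X, training_y=y)
        Kt = correlation_kernel(rng.normal(size=(3, 12)), X)
        assert np.allclose(predict_krr(model, Kt), Kt @ alpha)
        assert predict_krr(model, np.zeros((1, 8)))[0] == 0.0
        dup = np.vstack([Kt[0], Kt[0]])
        preds = predict_krr(model, dup)
        assert preds[0] == preds[1]

    def test_linear_ridge_approaches_ols(self, rng):
        X = rng.normal(size=(50, 5))
        y = rng.normal(size=50)
        w = fit_linear_ridge(X, y, 1e-8)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(w, ols, atol=1e-6)

    def test_primal_dual_identity(self, rng):
        # linear ridge == kernel ridge with the linear kernel at matched lambda
        X = rng.normal(size=(12, 7))
        y = rng.normal(size=12)
        lam = 2.5
        w = fit_linear_ridge(X, y, lam)
        alpha = fit_krr(X @ X.T, y, lam)
        Xt = rng.normal(size=(4, 7))
        assert np.allclose(
            predict_linear_ridge(w, Xt), (Xt @ X.T) @ alpha, atol=1e-8
        )

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_krr(np.eye(3), np.ones(3), 0.0)
        bad = np.eye(3)
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_krr(bad, np.ones(3), 1.0)
        with pytest.raises(ValueError):
            fit_linear_ridge(np.full((3, 2), np.nan), np.ones(3), 1.0)


class TestNestedCv:
    def test_single_element_grid(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        assert nested_cv_select_lambda(X, y, [3.3], seed=0) == 3.3

    def test_oversmoothing_rejected_on_strong_signal(self, rng):
        X = rng.normal(size=(60, 30))
        w = rng.normal(size=30)
        y = X @ w  # noiseless linear signal
        lam = nested_cv_select_lambda(X, y, [0.1, 1e6], seed=1)
        assert lam == 0.1

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(30, 15))
        y = rng.normal(size=30)
        grid = default_lambda_grid(30)
        a = nested_cv_select_lambda(X, y, grid, seed=5)
        b = nested_cv_select_lambda(X, y, grid, seed=5)
        assert a == b

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            nested_cv_select_lambda(rng.normal(size=(10, 5)),
                                    rng.normal(size=10), [])


class TestSubsampleTrainingPopulation:
    @pytest.fixture
    def table(self, tiny_dataset):
        return tiny_dataset.table()

    def test_majority_only_counts_match_minority_per_site(self, table):
        chosen = subsample_training_population(table, "majority_only", seed=0)
        grp = table.set_index("subject_id")
        assert all(grp.loc[s, "group"] == "majority" for s in chosen)
        for site, sub in table.groupby("site"):
            n_min = (sub.group == "minority").sum()
            n_maj = (sub.group == "majority").sum()
            expect = min(n_min, n_maj) if n_min else 0
            got = sum(grp.loc[s, "site"] == site for s in chosen)
            assert got == expect

    def test_reverse_trim_when_majority_scarce(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8)],
                "group": ["minority"] * 5 + ["majority"] * 3,
                "site": [0] * 8,
            }
        )
        mino = subsample_training_population(table, "minority_only", seed=1)
        majo = subsample_training_population(table, "majority_only", seed=1)
        assert len(mino) == 3 and len(majo) == 3

    def test_balanced_equal_totals(self, table):
        chosen = subsample_training_population(table, "balanced", seed=2)
        grp = table.set_index("subject_id")["group"]
        labels = [grp[s] for s in chosen]
        assert labels.count("minority") == labels.count("majority")

    def test_unknown_mode(self, table):
        with pytest.raises(ValueError):
            subsample_training_population(table, "everyone")


class TestSchemes:
    def test_abcd_enumerates_120_splits(self):
        combos = abcd_split_folds(10, 3)
        assert len(combos) == 120
        assert len(set(combos)) == 120


class TestEndToEndPrediction:
    def test_noiseless_shared_pattern_high_accuracy(self):
        from fairconn.experiments import single_split_prediction

        cfg = SyntheticConfig(
            n_majority=400, n_minority=100, n_roi=40, noise_sd=0.0,
            confound_loadings=(), pattern_similarity=1.0, seed=21,
        )
        ds = generate_dataset(cfg)
        out = single_split_prediction(
            ds, "y", seed=1, confound_policy="none",
            lambda_grid=(1e-8, 1e-6, 1e-4, 1e-2),
        )
        # the edge count (780) exceeds the training count, so even the
        # noiseless fit is a minimum-norm solution: high but not perfect
        assert out.r_majority > 0.9
        assert out.cod_majority > 0.8

    def test_permuted_scores_give_null_accuracy(self):
        from fairconn.experiments import single_split_prediction

        cfg = SyntheticConfig(n_majority=160, n_minority=40, n_roi=20, seed=22)
        ds = generate_dataset(cfg)
        rng = np.random.default_rng(0)
        rs = []
        for rep in range(5):
            ds.scores["y"] = rng.permutation(ds.scores["y"])
            out = single_split_prediction(ds, "y", seed=rep)
            rs.append(np.corrcoef(out.test_y_true, out.test_y_pred)[0, 1])
        assert abs(np.mean(rs)) < 0.15

    def test_confound_leakage_tripwire(self, rng):
        # a confound that perfectly predicts test y (but not train y) must
        # not inflate accuracy: the confound model is fitted on train only
        n_tr, n_te, p = 100, 40, 30
        fc = rng.normal(size=(n_tr + n_te, p))
        y = rng.normal(size=n_tr + n_te)
        conf = rng.normal(size=(n_tr + n_te, 1))
        conf[n_tr:, 0] = y[n_tr:]  # leak only in test rows
        model = fit_confound_model(y[:n_tr], fc[:n_tr], conf[:n_tr])
        y_tr, fc_tr = apply_confound_model(model, y[:n_tr], fc[:n_tr], conf[:n_tr])
        y_te, fc_te = apply_confound_model(model, y[n_tr:], fc[n_tr:], conf[n_tr:])
        alpha = fit_krr(correlation_kernel(fc_tr, fc_tr), y_tr, 1.0)
        y_hat = correlation_kernel(fc_te, fc_tr) @ alpha
        assert abs(np.corrcoef(y_te, y_hat)[0, 1]) < 0.4
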