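"""PLSR (NIPALS) and the back-propagation network."""

import numpy as np
import pytest

from libsquant.evaluation import make_folds, rmse
from libsquant.regressors import (
    MinMaxScaler1,
    TrainConfig,
    bpnn_init,
    bpnn_predict,
    bpnn_train,
    choose_n_components,
    default_hidden_size,
    n_parameters,
    plsr_fit,
    plsr_predict,
    vector_to_weights,
    weights_to_vector,
)


class TestPlsr:
    def test_univariate_single_component_is_ols_slope(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=25)
        y = 2.0 * x + rng.normal(0, 0.1, 25)
        model = plsr_fit(x[:, None], y, 1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert model.coef[0] == pytest.approx(slope, rel=1e-10)

    def test_full_rank_equals_least_squares_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 12))
        y = X @ rng.normal(size=12) + rng.normal(0, 0.1, 30)
        model = plsr_fit(X, y, 12)
        A = np.column_stack([np.ones(30), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(plsr_predict(model, X), A @ beta, atol=1e-8)

    def test_exact_linear_data_fits_perfectly(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 2))
        y = 3.0 * X[:, 0] - 2.0 * X[:, 1]
        model = plsr_fit(X, y, 2)
        assert rmse(y, plsr_predict(model, X)) == pytest.approx(0.0, abs=1e-10)

    def test_matches_sklearn_reference(self):
        """Independent cross-check against scikit-learn's PLS implementation."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 15))
        y = X @ rng.normal(size=15) + rng.normal(0, 0.5, 40)
        for k in (1, 3, 7):
            ours = plsr_predict(plsr_fit(X, y, k), X)
            sk = PLSRegression(n_components=k, scale=False).fit(X, y).predict(X).ravel()
            np.testing.assert_allclose(ours, sk, atol=1e-8)

    def test_rmsec_never_increases_with_components(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 1.0, 25)
        errs = [rmse(y, plsr_predict(plsr_fit(X, y, k), X)) for k in range(1, 9)]
        assert all(b <= a + 1e-10 for a, b in zip(errs, errs[1:]))

    def test_mean_spectrum_predicts_mean_response(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        model = plsr_fit(X, y, 3)
        assert plsr_predict(model, X.mean(axis=0)[None, :])[0] == pytest.approx(y.mean())

    def test_duplicated_row_duplicated_prediction(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = plsr_fit(X, y, 2)
        double = np.vstack([X[3], X[3]])
        p = plsr_predict(model, double)
        assert p[0] == p[1]

    def test_zero_variance_y_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            plsr_fit(np.random.default_rng(7).normal(size=(10, 3)), np.ones(10), 2)

    def test_choose_n_components_is_cv_argmin(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 20))
        y = X[:, 0] + X[:, 1] + rng.normal(0, 1.0, 60)  # noisy low-rank signal
        folds = make_folds(np.arange(60) % 6, k=5, seed=0)
        k = choose_n_components(X, y, folds, max_components=10)
        curve = []
        for kk in range(1, 11):
            preds = np.empty_like(y)
            for tr, te in folds:
                preds[te] = plsr_predict(plsr_fit(X[tr], y[tr], kk), X[te])
            curve.append(rmse(y, preds))
        assert curve[k - 1] == min(curve)
        # ties and near-ties resolve toward fewer components
        assert all(curve[k - 1] < c - 1e-12 for c in curve[: k - 1])


class TestScaling:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, size=(20, 4))
        scaler = MinMaxScaler1.fit(X)
        np.testing.assert_allclose(scaler.unscale(scaler.scale(X)), X, atol=1e-10)

    def test_range_maps_to_unit_box(self):
        X = np.array([[0.0, 10.0], [4.0, 30.0]])
        Z = MinMaxScaler1.fit(X).scale(X)
        np.testing.assert_allclose(Z, [[-1, -1], [1, 1]])


class TestBpnn:
    def test_init_deterministic_and_shaped(self):
        a = bpnn_init(4, 10, 1, seed=3)
        b = bpnn_init(4, 10, 1, seed=3)
        np.testing.assert_array_equal(a.W1, b.W1)
        assert a.W1.shape == (10, 4) and a.W2.shape == (1, 10)
        c = bpnn_init(4, 10, 1, seed=4)
        assert not np.array_equal(a.W1, c.W1)
        assert np.all(np.abs(a.W1) <= 1)

    def test_zero_epochs_leaves_weights_untouched(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(10, 3)), rng.normal(size=10)
        model = bpnn_init(3, 5, 1, seed=0)
        W1 = model.W1.copy()
        model, history = bpnn_train(model, X, y, TrainConfig(epochs=0))
        np.testing.assert_array_equal(model.W1, W1)
        assert history == []

    def test_learns_linear_map_within_default_budget(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 50)[:, None]
        y = 2.0 * x.ravel() + 1.0
        best = np.inf
        for seed in range(5):
            model = bpnn_init(1, 5, 1, seed=seed)
            model, _ = bpnn_train(model, x, y, TrainConfig(seed=seed))
            best = min(best, rmse(y, bpnn_predict(model, x)))
        assert best < 0.05

    def test_solves_xor(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        t = np.array([0.0, 1.0, 1.0, 0.0])
        best = np.inf
        for seed in range(5):
            model = bpnn_init(2, 4, 1, seed=seed)
            model, _ = bpnn_train(model, X, t, TrainConfig(epochs=5000, learning_rate=0.3,
                                                          seed=seed))
            best = min(best, float(np.mean((bpnn_predict(model, X) - t) ** 2)))
        assert best < 0.05

    def test_loss_history_finite_and_decreasing_on_linear_problem(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        y = X @ [1.0, -1.0]
        model = bpnn_init(2, 4, 1, seed=0)
        _, history = bpnn_train(model, X, y, TrainConfig(epochs=300, learning_rate=0.001))
        assert np.all(np.isfinite(history))
        assert all(b <= a + 1e-12 for a, b in zip(history[1:], history[2:]))

    def test_zero_weight_network_predicts_bias(self):
        model = bpnn_init(3, 5, 1, seed=0)
        model.W1[:] = 0; model.b1[:] = 0; model.W2[:] = 0; model.b2[:] = 0.5
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(8, 3)), rng.normal(size=8)
        from libsquant.regressors import bpnn_fit_scalers
        bpnn_fit_scalers(model, X, y)
        preds = bpnn_predict(model, X)
        expected = model.y_scaler.unscale(np.array([[0.5]]))[0, 0]
        np.testing.assert_allclose(preds, expected)

    def test_prediction_deterministic_and_permutation_equivariant(self):
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(12, 4)), rng.normal(size=12)
        model = bpnn_init(4, 6, 1, seed=1)
        model, _ = bpnn_train(model, X, y, TrainConfig(epochs=50))
        p1 = bpnn_predict(model, X)
        p2 = bpnn_predict(model, X)
        np.testing.assert_array_equal(p1, p2)
        perm = rng.permutation(12)
        np.testing.assert_array_equal(bpnn_predict(model, X[perm]), p1[perm])

    def test_hidden_size_heuristic(self):
        assert default_hidden_size(6, 1) == 7
        assert default_hidden_size(45, 1) == 11


class TestParameterVector:
    @pytest.mark.parametrize("shape,expected", [((4, 10, 1), 61), ((6, 10, 1), 81)])
    def test_parameter_counts(self, shape, expected):
        assert n_parameters(*shape) == expected

    def test_round_trip_identity(self):
        model = bpnn_init(5, 7, 2, seed=9)
        theta = weights_to_vector(model)
        back = vector_to_weights(theta, (5, 7, 2))
        np.testing.assert_array_equal(back.W1, model.W1)
        np.testing.assert_array_equal(back.b1, model.b1)
        np.testing.assert_array_equal(back.W2, model.W2)
        np.testing.assert_array_equal(back.b2, model.b2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="expected 61"):
            vector_to_weights(np.zeros(60), (4, 10, 1))
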