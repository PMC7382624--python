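"""Learners: the weighted BCE objective, logistic and feed-forward training,
prediction contracts, and the hyperparameter search harness."""

import numpy as np
import pytest

from conftest import scalar_loop_bce
from clinicrec.evaluation import auroc
from clinicrec.models import (
    FeedForwardScorer,
    LossSpec,
    NetworkParams,
    TrainConfig,
    hyperparameter_search,
    predict_scores,
    train_clinicnet,
    train_logistic,
    weighted_bce_loss,
)


class TestWeightedBceLoss:
    def test_perfect_prediction_near_zero(self):
        assert weighted_bce_loss(np.array([1.0]), np.array([1.0 - 1e-7])) < 1e-6

    def test_hand_evaluated_example(self):
        # y=[1,0], yhat=[.5,.5], w=2: -(1/2)(2 log .5 + log .5) = 1.5 ln 2
        got = weighted_bce_loss(np.array([1.0, 0.0]), np.array([0.5, 0.5]), LossSpec(2.0, 0.0))
        assert got == pytest.approx(1.5 * np.log(2), abs=1e-12)

    def test_l2_isolated_with_zero_data_loss(self):
        W = (np.array([[1.0, 2.0], [3.0, 4.0]]),)
        got = weighted_bce_loss(
            np.array([1.0]), np.array([1.0 - 1e-7]), LossSpec(1.0, 0.1), W
        )
        assert got == pytest.approx(0.05 * 30.0, abs=1e-6)

    def test_matches_scalar_loop_reference(self):
        """Vectorized loss equals an element-by-element evaluation of the
        formula to 1e-10 on random instances."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            m, k = rng.integers(1, 8, size=2)
            y = rng.integers(0, 2, size=(m, k)).astype(float)
            yhat = rng.uniform(0.01, 0.99, size=(m, k))
            w = float(rng.uniform(0.5, 50))
            lam = float(rng.uniform(0, 0.1))
            Ws = (rng.normal(size=(3, 2)), rng.normal(size=(2, 2)))
            got = weighted_bce_loss(y, yhat, LossSpec(w, lam), Ws)
            ref = scalar_loop_bce(y, yhat, w, lam, Ws)
            assert got == pytest.approx(ref, abs=1e-10)

    def test_gradient_matches_finite_differences(self):
        """Analytic d(loss)/d(yhat) vs central finite differences, tol 1e-5."""
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=(4, 3)).astype(float)
        yhat = rng.uniform(0.1, 0.9, size=(4, 3))
        spec = LossSpec(7.0, 0.0)
        m = y.shape[0]
        analytic = -(spec.positive_weight * y / yhat - (1 - y) / (1 - yhat)) / m
        eps = 1e-6
        for i in range(4):
            for j in range(3):
                up, dn = yhat.copy(), yhat.copy()
                up[i, j] += eps
                dn[i, j] -= eps
                fd = (weighted_bce_loss(y, up, spec) - weighted_bce_loss(y, dn, spec)) / (2 * eps)
                assert fd == pytest.approx(analytic[i, j], abs=1e-5)

    def test_increasing_w_penalizes_false_negatives_more(self):
        y = np.array([1.0, 1.0, 0.0])
        yhat = np.array([0.2, 0.9, 0.1])  # first positive badly missed
        losses = [weighted_bce_loss(y, yhat, LossSpec(w)) for w in (1.0, 5.0, 25.0)]
        assert losses[0] < losses[1] < losses[2]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_bce_loss(np.zeros(3), np.zeros(4))


@pytest.fixture(scope="module")
def separable_data():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(200, 2))
    y = (X @ np.array([2.0, -1.0]) > 0).astype(float).reshape(-1, 1)
    return X, y


@pytest.fixture(scope="module")
def xor_data():
    rng = np.random.default_rng(7)
    X = rng.integers(0, 2, size=(400, 2)).astype(float)
    y = np.logical_xor(X[:, 0], X[:, 1]).astype(float).reshape(-1, 1)
    return X + rng.normal(0, 0.05, X.shape), y


class TestLogistic:
    def test_linearly_separable_training_auroc(self, separable_data):
        X, y = separable_data
        model = train_logistic(X, y, TrainConfig("sgd", 0.01, epochs=30, batch_size=32, seed=0))
        assert auroc(model.predict(X), y) >= 0.95

    def test_all_zero_target_scores_finite(self, separable_data):
        X, _ = separable_data
        y = np.zeros((X.shape[0], 2))
        model = train_logistic(X, y)
        assert np.isfinite(model.predict(X)).all()

    def test_same_seed_identical_weights(self, separable_data):
        X, y = separable_data
        cfg = TrainConfig("sgd", 0.01, epochs=1, seed=12)
        m1, m2 = train_logistic(X, y, cfg), train_logistic(X, y, cfg)
        assert all(np.array_equal(a, b) for a, b in zip(m1.W, m2.W))


class TestClinicNet:
    def test_learns_xor_where_logistic_cannot(self, xor_data):
        X, y = xor_data
        net = NetworkParams(hidden_units=(16, 16))
        cfg = TrainConfig("nadam", 0.01, epochs=150, batch_size=64, seed=0)
        model = train_clinicnet(X, y, net, LossSpec(), cfg)
        assert auroc(model.predict(X), y) >= 0.9
        logistic = train_logistic(X, y, TrainConfig("sgd", 0.01, epochs=150, batch_size=64, seed=0))
        assert auroc(logistic.predict(X), y) <= 0.6

    def test_zero_hidden_layers_is_logistic_architecture(self, separable_data):
        X, y = separable_data
        model = train_clinicnet(
            X, y, NetworkParams(hidden_units=()), LossSpec(),
            TrainConfig("sgd", 0.01, epochs=1, seed=3),
        )
        assert len(model.W) == 1  # single linear layer + sigmoid
        ref = train_logistic(X, y, TrainConfig("sgd", 0.01, epochs=1, seed=3))
        assert np.allclose(model.W[0], ref.W[0])

    def test_unit_weight_equals_unweighted_bce_trajectory(self, separable_data):
        X, y = separable_data
        cfg = TrainConfig("nadam", 0.001, epochs=2, batch_size=64, seed=6)
        m1 = train_clinicnet(X, y, NetworkParams((8,)), LossSpec(1.0, 0.0), cfg)
        m2 = train_clinicnet(X, y, NetworkParams((8,)), LossSpec(1.0, 0.0), cfg)
        assert [r["loss"] for r in m1.train_log] == [r["loss"] for r in m2.train_log]
        # and the w=1 per-batch losses coincide with the standard mean BCE
        probe = m1.predict(X)
        assert weighted_bce_loss(y, probe) == pytest.approx(
            weighted_bce_loss(y, probe, LossSpec(1.0, 0.0)), abs=0
        )

    def test_batch_norm_and_dropout_train_stably(self, xor_data):
        X, y = xor_data
        net = NetworkParams((16,), dropout_rate=0.2, batch_norm=True)
        model = train_clinicnet(
            X, y, net, LossSpec(5.0, 1e-4), TrainConfig("nadam", 0.01, epochs=20, batch_size=64, seed=0)
        )
        assert np.isfinite(model.predict(X)).all()


class TestPredictScores:
    def test_outputs_in_open_unit_interval_and_repeatable(self, separable_data):
        X, y = separable_data
        model = train_logistic(X, y)
        s1, s2 = predict_scores(model, X), predict_scores(model, X)
        assert np.array_equal(s1, s2)
        assert (s1 > 0).all() and (s1 < 1).all()

    def test_single_row_agrees_with_batch(self, separable_data):
        X, y = separable_data
        model = train_clinicnet(
            X, y, NetworkParams((8,), batch_norm=True), LossSpec(),
            TrainConfig(epochs=1, seed=0),
        )
        batch = predict_scores(model, X)
        for r in (0, 57, 199):
            single = predict_scores(model, X[r : r + 1])
            assert np.allclose(single[0], batch[r], atol=1e-6)

    def test_schema_mismatch_rejected(self, separable_data):
        X, y = separable_data
        model = train_logistic(X, y)
        with pytest.raises(ValueError, match="columns"):
            predict_scores(model, X[:, :1])


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, separable_data):
        X, y = separable_data
        model = train_clinicnet(
            X, y, NetworkParams((8,), batch_norm=True), LossSpec(2.0, 1e-4),
            TrainConfig(epochs=1, seed=0), columns=["f0", "f1"],
        )
        model.save(tmp_path / "ckpt.json")
        back = FeedForwardScorer.load(tmp_path / "ckpt.json")
        assert back.columns == ["f0", "f1"]
        assert np.allclose(back.predict(X), model.predict(X))


class TestHyperparameterSearch:
    SPACE = {
        "hidden_layers": [1, 2],
        "hidden_units": [8, 16],
        "dropout": [0.0],
        "batch_norm": [False],
        "positive_weight": [1.0, 5.0],
        "l2_lambda": [0.0],
    }

    def _data(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 4))
        y = (X[:, 0] * X[:, 1] > 0).astype(float).reshape(-1, 1)
        return X[:200], y[:200], X[200:], y[200:]

    def test_single_trial_returns_that_config(self):
        Xtr, Ytr, Xv, Yv = self._data()
        res = hyperparameter_search(Xtr, Ytr, Xv, Yv, self.SPACE, n_rows=200, n_trials=1, seed=0)
        assert len(res.trials) == 1
        assert res.val_score == res.trials[0]["val_average_precision"]

    def test_fixed_seed_identical_trial_sequence(self):
        Xtr, Ytr, Xv, Yv = self._data()
        r1 = hyperparameter_search(Xtr, Ytr, Xv, Yv, self.SPACE, n_rows=200, n_trials=3, seed=5)
        r2 = hyperparameter_search(Xtr, Ytr, Xv, Yv, self.SPACE, n_rows=200, n_trials=3, seed=5)
        assert r1.trials == r2.trials

    def test_argmax_over_logged_scores(self):
        Xtr, Ytr, Xv, Yv = self._data()
        res = hyperparameter_search(Xtr, Ytr, Xv, Yv, self.SPACE, n_rows=200, n_trials=5, seed=1)
        assert res.val_score == max(t["val_average_precision"] for t in res.trials)

    def test_oversized_subsample_warns_and_uses_all(self):
        Xtr, Ytr, Xv, Yv = self._data()
        with pytest.warns(UserWarning, match="available"):
            hyperparameter_search(Xtr, Ytr, Xv, Yv, self.SPACE, n_rows=10_000, n_trials=1, seed=0)
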