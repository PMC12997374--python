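"""RBM energy model, CD-1 learning and supervised fine-tuning."""

import itertools

import numpy as np
import pytest

from spiralselect.dbnn import (DBNNClassifier, DBNNModel, RBMParams,
                               TrainConfig, _loss_and_grads, cd1_step,
                               energy, hidden_given_visible, init_rbm,
                               predict_proba, pretrain_stack,
                               reconstruction_error, sigmoid, train_rbm,
                               visible_given_hidden)


def boltzmann_distribution(rbm):
    """Exact p(v, h) by enumerating every binary state (oracle)."""
    vs = np.array(list(itertools.product([0, 1], repeat=rbm.n_visible)),
                  dtype=float)
    hs = np.array(list(itertools.product([0, 1], repeat=rbm.n_hidden)),
                  dtype=float)
    E = np.array([[energy(rbm, v, h) for h in hs] for v in vs])
    P = np.exp(-E)
    return vs, hs, P / P.sum()


class TestEnergy:
    def test_zero_parameters_give_zero_energy(self):
        rbm = RBMParams(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        for v in itertools.product([0, 1], repeat=2):
            for h in itertools.product([0, 1], repeat=2):
                assert energy(rbm, np.array(v), np.array(h)) == 0.0

    def test_zero_state_has_zero_energy_for_any_parameters(self):
        rng = np.random.default_rng(0)
        rbm = init_rbm(3, 2, rng, scale=1.0)
        rbm.a += rng.standard_normal(3)
        assert energy(rbm, np.zeros(3), np.zeros(2)) == 0.0

    def test_hand_value(self):
        rbm = RBMParams(np.ones((2, 1)), np.zeros(2), np.zeros(1))
        assert energy(rbm, np.array([1.0, 1.0]), np.array([1.0])) == -2.0

    def test_dimension_mismatch_errors(self):
        rbm = init_rbm(3, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            energy(rbm, np.zeros(4), np.zeros(2))


class TestConditionals:
    def test_zero_parameters_give_half(self):
        rbm = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        np.testing.assert_allclose(hidden_given_visible(rbm, np.ones(3)), 0.5)
        np.testing.assert_allclose(visible_given_hidden(rbm, np.ones(2)), 0.5)

    def test_probabilities_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(1)
        rbm = init_rbm(4, 3, rng, scale=2.0)
        p = hidden_given_visible(rbm, rng.integers(0, 2, (10, 4)))
        assert ((p > 0) & (p < 1)).all()

    def test_gibbs_chain_reaches_boltzmann_stationary_distribution(self):
        """Block Gibbs sampling from the module conditionals must sample
        the exact enumeration distribution of a 3x2 energy model."""
        rng = np.random.default_rng(5)
        rbm = init_rbm(3, 2, rng, scale=0.8)
        rbm.a += 0.3
        rbm.b -= 0.2
        vs, hs, P = boltzmann_distribution(rbm)

        g = np.random.default_rng(7)
        v = np.zeros(3)
        counts = np.zeros((8, 4))
        for s in range(30000):
            ph = hidden_given_visible(rbm, v)
            h = (g.random(2) < ph).astype(float)
            pv = visible_given_hidden(rbm, h)
            v = (g.random(3) < pv).astype(float)
            if s > 1000:  # burn-in
                counts[int(v @ [4, 2, 1]), int(h @ [2, 1])] += 1
        emp = counts / counts.sum()
        assert np.abs(emp - P).max() < 0.01


class TestCD1:
    def test_zero_learning_rate_freezes_parameters(self):
        rng = np.random.default_rng(2)
        rbm = init_rbm(3, 2, rng)
        cfg = TrainConfig(learning_rate=1e-30)
        new, _ = cd1_step(rbm, np.eye(3), cfg, rng)
        np.testing.assert_allclose(new.W, rbm.W, atol=1e-25)

    def test_reconstruction_error_drops_during_training(self):
        """Two well-separated binary modes: 50 epochs of CD-1 must
        reconstruct better than the random initialization."""
        rng = np.random.default_rng(3)
        modes = np.array([[1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]],
                         dtype=float)
        data = modes[rng.integers(0, 2, 200)]
        cfg = TrainConfig(epochs=50, learning_rate=0.05, seed=3)
        rbm0 = init_rbm(6, 4, np.random.default_rng(cfg.seed))
        err0 = reconstruction_error(rbm0, data)
        rbm, history = train_rbm(data, 4, cfg, np.random.default_rng(cfg.seed))
        assert history[-1] < err0
        assert reconstruction_error(rbm, data) < err0

    def test_empty_batch_rejected(self):
        rbm = init_rbm(2, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            cd1_step(rbm, np.empty((0, 2)), TrainConfig(),
                     np.random.default_rng(0))


class TestPretrainStack:
    def test_stack_shapes_follow_architecture(self):
        data = np.random.default_rng(0).random((40, 7))
        stack = pretrain_stack(data, (64, 32), TrainConfig(epochs=1))
        assert (stack[0].W.shape, stack[1].W.shape) == ((7, 64), (64, 32))

    def test_zero_epochs_equals_seeded_initialization(self):
        data = np.random.default_rng(0).random((20, 5))
        cfg = TrainConfig(epochs=0, seed=9)
        stack = pretrain_stack(data, (4, 3), cfg)
        rng = np.random.default_rng(9)
        expected0 = init_rbm(5, 4, rng)
        np.testing.assert_array_equal(stack[0].W, expected0.W)
        # fan-balanced init bound
        assert np.abs(stack[0].W).max() <= np.sqrt(6.0 / 9.0)

    def test_deterministic_under_fixed_seed(self):
        data = np.random.default_rng(1).random((30, 6))
        cfg = TrainConfig(epochs=3, seed=4)
        a = pretrain_stack(data, (5, 3), cfg)
        b = pretrain_stack(data, (5, 3), cfg)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.W, rb.W)


class TestBackprop:
    def _random_net(self, rng):
        weights = [0.5 * rng.standard_normal((5, 4)),
                   0.5 * rng.standard_normal((4, 3)),
                   0.5 * rng.standard_normal((3, 2))]
        biases = [rng.standard_normal(4), rng.standard_normal(3),
                  rng.standard_normal(2)]
        return weights, biases

    @pytest.mark.parametrize("with_dropout", [False, True])
    def test_analytic_gradient_matches_finite_differences(self,
                                                          with_dropout):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 5))
        Y = np.eye(2)[rng.integers(0, 2, 4)]
        weights, biases = self._random_net(rng)
        masks = None
        if with_dropout:
            keep = 0.7
            masks = [(rng.random((4, w.shape[1])) < keep) / keep
                     for w in weights[:-1]]
        _, gw, gb = _loss_and_grads(weights, biases, X, Y, 1e-3, masks)
        eps = 1e-6
        for li in range(3):
            for idx in [(0, 0), (1, 1)]:
                weights[li][idx] += eps
                lp, _, _ = _loss_and_grads(weights, biases, X, Y, 1e-3,
                                           masks)
                weights[li][idx] -= 2 * eps
                lm, _, _ = _loss_and_grads(weights, biases, X, Y, 1e-3,
                                           masks)
                weights[li][idx] += eps
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(gw[li][idx], rel=1e-5,
                                            abs=1e-8)
            biases[li][0] += eps
            lp, _, _ = _loss_and_grads(weights, biases, X, Y, 1e-3, masks)
            biases[li][0] -= 2 * eps
            lm, _, _ = _loss_and_grads(weights, biases, X, Y, 1e-3, masks)
            biases[li][0] += eps
            assert (lp - lm) / (2 * eps) == pytest.approx(gb[li][0],
                                                          rel=1e-5,
                                                          abs=1e-8)


class TestFinetune:
    def _toy(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 4))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        return X, y

    def test_capacity_on_separable_toy_data(self):
        X, y = self._toy()
        cfg = TrainConfig(epochs=5, finetune_epochs=500, patience=200,
                          learning_rate=0.2, dropout_rate=0.0, seed=1)
        clf = DBNNClassifier((16, 8), cfg).fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.97

    def test_returned_snapshot_beats_final_epoch(self):
        X, y = self._toy(seed=2)
        cfg = TrainConfig(epochs=3, finetune_epochs=120, patience=120,
                          learning_rate=0.05, seed=2)
        clf = DBNNClassifier((8, 4), cfg).fit(X, y)
        h = clf.model.train_history
        assert h["best_valid_loss"] <= h["valid_loss"][-1] + 1e-12
        assert h["best_valid_loss"] <= min(h["valid_loss"]) + 1e-12

    def test_empty_validation_split_rejected(self):
        from spiralselect.dbnn import finetune
        stack = pretrain_stack(np.random.default_rng(0).random((10, 3)),
                               (4,), TrainConfig(epochs=0))
        model = DBNNModel.from_stack(stack)
        with pytest.raises(ValueError):
            finetune(model, np.zeros((10, 3)), np.zeros(10, dtype=int),
                     np.empty((0, 3)), np.empty(0, dtype=int),
                     TrainConfig())


class TestPredictProba:
    def test_rows_sum_to_one_and_are_deterministic(self):
        X, y = np.random.default_rng(0).standard_normal((30, 3)), \
            np.random.default_rng(1).integers(0, 2, 30)
        cfg = TrainConfig(epochs=2, finetune_epochs=20, patience=5, seed=0)
        clf = DBNNClassifier((6, 3), cfg).fit(X, y)
        p = clf.predict_proba(np.vstack([X[:5], X[:5]]))
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
        np.testing.assert_array_equal(p[:5], p[5:])

    def test_zero_weight_head_predicts_half(self):
        stack = [init_rbm(3, 4, np.random.default_rng(0))]
        model = DBNNModel.from_stack(stack)
        model.weights[-1][:] = 0.0
        model.biases[-1][:] = 0.0
        p = predict_proba(model, np.random.default_rng(1).random((6, 3)))
        np.testing.assert_allclose(p, 0.5)

    def test_feature_count_mismatch_errors(self):
        stack = [init_rbm(3, 4, np.random.default_rng(0))]
        model = DBNNModel.from_stack(stack)
        with pytest.raises(ValueError, match="features"):
            predict_proba(model, np.zeros((2, 5)))
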