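"""Recurrent decoder: closed-form cell checks, gradient agreement, training."""

import numpy as np
import pytest

import eegverb.dual_lstm as dl
from eegverb.dual_lstm import (
    LstmLayerParams,
    TrainConfig,
    TrainingDivergedError,
    cross_entropy_loss,
    exact_line_search,
    fc_forward,
    forward,
    forward_batch,
    init_network,
    lstm_step,
)


def _numeric_grad(net, x, y, h=1e-5):
    p0 = net.get_flat()
    probe = net.copy()
    num = np.empty_like(p0)
    for i in range(len(p0)):
        p = p0.copy()
        p[i] += h
        probe.set_flat(p)
        lp = cross_entropy_loss(forward_batch(probe, x), y)
        p[i] -= 2 * h
        probe.set_flat(p)
        lm = cross_entropy_loss(forward_batch(probe, x), y)
        num[i] = (lp - lm) / (2 * h)
    return num


class TestFcForward:
    def test_identity_weights(self):
        x = np.random.default_rng(0).standard_normal((4, 5))
        out = fc_forward(x, (np.eye(5), np.zeros(5)), activation="linear")
        np.testing.assert_array_equal(out, x)

    def test_zero_weights_give_activated_bias(self):
        x = np.random.default_rng(1).standard_normal((3, 5))
        b = np.array([0.5, -0.5, 1.0])
        out = fc_forward(x, (np.zeros((5, 3)), b))
        np.testing.assert_allclose(out, np.tile(np.tanh(b), (3, 1)))

    def test_matches_matrix_arithmetic(self):
        rng = np.random.default_rng(2)
        x, w, b = rng.standard_normal((6, 4)), rng.standard_normal((4, 3)), rng.standard_normal(3)
        np.testing.assert_allclose(fc_forward(x, (w, b), "linear"), x @ w + b,
                                   atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            fc_forward(np.zeros((2, 4)), (np.zeros((5, 3)), np.zeros(3)))


class TestLstmStep:
    def test_zero_parameters_closed_form(self):
        """All-zero transforms: sigmoid gates 0.5, modulation 0."""
        h = 3
        params = LstmLayerParams(np.zeros((4, 4 * h)), np.zeros((h, 4 * h)),
                                 np.zeros(4 * h))
        c_prev = np.array([[0.2, -1.0, 3.0]])
        h_t, c_t = lstm_step(np.ones((1, 4)), np.zeros((1, h)), c_prev, params)
        np.testing.assert_allclose(c_t, 0.5 * c_prev, atol=1e-14)
        np.testing.assert_allclose(h_t, 0.5 * np.tanh(0.5 * c_prev), atol=1e-14)

    def test_all_zero_state_stays_zero(self):
        h = 2
        params = LstmLayerParams(np.zeros((3, 4 * h)), np.zeros((h, 4 * h)),
                                 np.zeros(4 * h))
        h_t, c_t = lstm_step(np.zeros((1, 3)), np.zeros((1, h)),
                             np.zeros((1, h)), params)
        np.testing.assert_array_equal(h_t, 0.0)
        np.testing.assert_array_equal(c_t, 0.0)

    def test_non_finite_input_rejected(self):
        h = 2
        params = LstmLayerParams(np.zeros((3, 4 * h)), np.zeros((h, 4 * h)),
                                 np.zeros(4 * h))
        with pytest.raises(FloatingPointError):
            lstm_step(np.array([[np.nan, 0, 0]]), np.zeros((1, h)),
                      np.zeros((1, h)), params)


class TestGradients:
    def test_single_cell_gradient_matches_finite_differences(self):
        """3-unit cell (no FC stack): backprop vs central differences."""
        net = init_network(4, fc_sizes=(), lstm_sizes=(3,), n_classes=2, seed=1)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 4, 4))
        y = np.eye(2)[[0, 1]]
        _, grads = dl.backward_batch(net, x, y)
        g = np.concatenate([a.ravel() for a in grads])
        num = _numeric_grad(net, x, y)
        assert np.abs(g - num).max() <= 1e-5 * np.maximum(1.0, np.abs(num)).max()
        big = np.abs(num) > 1e-3
        assert np.all(np.abs(g[big] - num[big]) / np.abs(num[big]) <= 1e-5)

    def test_full_network_gradient_matches_finite_differences(self):
        """Miniature 7-layer network (FC stack + double LSTM), 5 time steps."""
        net = init_network(4, fc_sizes=(3, 3, 3), lstm_sizes=(3, 3),
                           n_classes=3, seed=0)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 5, 4))
        y = np.eye(3)[[0, 2]]
        _, grads = dl.backward_batch(net, x, y)
        g = np.concatenate([a.ravel() for a in grads])
        num = _numeric_grad(net, x, y)
        assert np.abs(g - num).max() <= 1e-5 * np.maximum(1.0, np.abs(num)).max()
        big = np.abs(num) > 1e-3
        assert np.all(np.abs(g[big] - num[big]) / np.abs(num[big]) <= 1e-5)


class TestForward:
    def test_softmax_contract(self):
        net = init_network(6, fc_sizes=(4,), lstm_sizes=(4,), n_classes=6, seed=3)
        pred = forward(net, np.random.default_rng(3).standard_normal((10, 6)))
        assert abs(pred.probs.sum() - 1.0) < 1e-9
        assert np.all(pred.probs >= 0)
        assert pred.label == int(pred.probs.argmax())

    def test_zero_initialised_network_is_uniform(self):
        net = init_network(6, fc_sizes=(4,), lstm_sizes=(4,), n_classes=6,
                           seed=0, zero_init=True)
        pred = forward(net, np.random.default_rng(4).standard_normal((10, 6)))
        np.testing.assert_allclose(pred.probs, 1.0 / 6.0, atol=1e-12)

    def test_output_permutation_equivariance(self):
        net = init_network(5, fc_sizes=(4,), lstm_sizes=(4,), n_classes=4, seed=5)
        x = np.random.default_rng(5).standard_normal((7, 5))
        base = forward(net, x).probs
        perm = np.array([2, 0, 3, 1])
        w, b = net.output_weights
        net.output_weights = (w[:, perm], b[perm])
        np.testing.assert_allclose(forward(net, x).probs, base[perm], atol=1e-12)

    def test_empty_sequence_rejected(self):
        net = init_network(5, fc_sizes=(4,), lstm_sizes=(4,), n_classes=3, seed=6)
        with pytest.raises(ValueError):
            forward_batch(net, np.empty((1, 0, 5)))


class TestLoss:
    def test_exact_onehot_prediction_is_zero(self):
        y = np.eye(6)[[2, 4]]
        assert cross_entropy_loss(y, y) < 1e-9

    def test_hand_computed_single_sample(self):
        """True unit at 0.5 contributes -ln 0.5; off units -ln(1 - a)."""
        probs = np.array([[0.5, 0.1, 0.1, 0.1, 0.1, 0.1]])
        y = np.eye(6)[[0]]
        expect = -(np.log(0.5) + 5 * np.log(0.9))
        assert abs(cross_entropy_loss(probs, y) - expect) < 1e-12
        assert abs(-np.log(0.5) - 0.6931) < 1e-4

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(7)
        logits = rng.standard_normal((10, 6))
        probs = dl.softmax(logits)
        y = np.eye(6)[rng.integers(0, 6, 10)]
        manual = np.mean([
            -sum(y[i, k] * np.log(probs[i, k])
                 + (1 - y[i, k]) * np.log(1 - probs[i, k]) for k in range(6))
            for i in range(10)])
        assert abs(cross_entropy_loss(probs, y) - manual) < 1e-12


class TestLineSearch:
    def test_scalar_quadratic(self):
        f = lambda v: float(v @ v)
        alpha = exact_line_search(f, np.array([1.0]), np.array([2.0]))
        assert abs(alpha - 0.5) < 1e-6
        x_new = 1.0 - alpha * 2.0
        assert abs(x_new) < 1e-6

    @pytest.mark.parametrize("seed", range(3))
    def test_spd_quadratic_matches_closed_form(self, seed):
        """Steepest-descent exact step: alpha = g'g / g'Ag; successive
        gradients orthogonal."""
        rng = np.random.default_rng(seed)
        m = rng.standard_normal((5, 5))
        a = m @ m.T + 5 * np.eye(5)
        x0 = rng.standard_normal(5)
        g = a @ x0
        f = lambda v: float(0.5 * v @ a @ v)
        alpha = exact_line_search(f, x0, g)
        assert abs(alpha - (g @ g) / (g @ a @ g)) < 1e-8
        g_new = a @ (x0 - alpha * g)
        cosine = g_new @ g / (np.linalg.norm(g_new) * np.linalg.norm(g) + 1e-30)
        assert abs(cosine) < 0.05

    def test_zero_gradient_rejected(self):
        with pytest.raises(ValueError):
            exact_line_search(lambda v: float(v @ v), np.zeros(3), np.zeros(3))

    def test_descent_non_increasing_on_convex_problem(self):
        rng = np.random.default_rng(9)
        m = rng.standard_normal((4, 4))
        a = m @ m.T + np.eye(4)
        x = rng.standard_normal(4)
        f = lambda v: float(0.5 * v @ a @ v)
        losses = [f(x)]
        for _ in range(6):
            g = a @ x
            x = x - exact_line_search(f, x, g) * g
            losses.append(f(x))
        assert all(b <= a_ + 1e-12 for a_, b in zip(losses, losses[1:]))

    def test_network_line_search_orthogonalises_gradient(self):
        net = init_network(4, fc_sizes=(4,), lstm_sizes=(4,), n_classes=3, seed=11)
        rng = np.random.default_rng(11)
        x = rng.standard_normal((12, 6, 4))
        y = np.eye(3)[rng.integers(0, 3, 12)]
        _, grads = dl.backward_batch(net, x, y)
        g = np.concatenate([a.ravel() for a in grads])
        alpha = dl.line_search_lr(net, x, y, grads)
        probe = net.copy()
        probe.set_flat(net.get_flat() - alpha * g)
        _, grads2 = dl.backward_batch(probe, x, y)
        g2 = np.concatenate([a.ravel() for a in grads2])
        cosine = g @ g2 / (np.linalg.norm(g) * np.linalg.norm(g2) + 1e-30)
        assert abs(cosine) < 0.05


class TestTraining:
    def _toy_data(self, n=40, steps=10, dim=3, seed=12):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        x = rng.standard_normal((n, steps, dim)) * 0.3
        x += np.where(labels[:, None, None] == 0, 0.6, -0.6)
        return x, labels

    def test_linearly_separable_sequences_reach_perfect_accuracy(self):
        x, labels = self._toy_data()
        net = init_network(3, fc_sizes=(8,), lstm_sizes=(8,), n_classes=2, seed=12)
        cfg = TrainConfig(learning_rate=0.05, batch_size=8, max_epochs=200,
                          seed=12)
        net, trace = dl.train(net, x, labels, cfg)
        assert trace.train_acc.iloc[-1] == 1.0
        assert (trace.train_acc == 1.0).idxmax() < 200

    def test_seeded_training_is_bitwise_deterministic(self):
        x, labels = self._toy_data(n=16)
        runs = []
        for _ in range(2):
            net = init_network(3, fc_sizes=(4,), lstm_sizes=(4,), n_classes=2,
                               seed=2)
            net, trace = dl.train(net, x, labels,
                                  TrainConfig(max_epochs=5, seed=2))
            runs.append((net.get_flat(), trace))
        np.testing.assert_array_equal(runs[0][0], runs[1][0])
        assert runs[0][1].equals(runs[1][1])

    def test_frames_reshape_preserves_samples(self):
        import eegverb as ev

        rng = np.random.default_rng(13)
        data = rng.standard_normal((2, 3, 40))
        ts = ev.TrialSet(data, [0, 1], [0, 0], [0, 0],
                         ("F5", "FT7", "FC5"), 250.0)
        x = dl.frames_from_trials(ts, frame_len=10, standardize=False)
        assert x.shape == (2, 4, 30)
        np.testing.assert_array_equal(x[0, 1].reshape(3, 10), data[0, :, 10:20])
        with pytest.raises(ValueError):
            dl.frames_from_trials(ts, frame_len=7)

    def test_instability_at_large_rates(self):
        """Unclipped gradient descent degrades once the step size crosses
        the stability threshold — the fluctuation/divergence mechanism
        behind learning-rate tuning."""
        rng = np.random.default_rng(14)
        labels = rng.integers(0, 2, 60)
        x = rng.standard_normal((60, 10, 3))
        x += np.where(labels[:, None, None] == 0, 0.25, -0.25)
        accs = {}
        for lr in (0.05, 8.0):
            net = init_network(3, fc_sizes=(8,), lstm_sizes=(8,), n_classes=2,
                               seed=14)
            cfg = TrainConfig(learning_rate=lr, batch_size=8, max_epochs=80,
                              seed=14, clip_norm=0.0)
            try:
                net, trace = dl.train(net, x, labels, cfg)
                accs[lr] = trace.train_acc.iloc[-1]
            except TrainingDivergedError:
                accs[lr] = 0.0
        assert accs[0.05] == 1.0
        assert accs[8.0] < accs[0.05]
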