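import numpy as np
import pytest

from gdglcm.classifiers import (
    MLPModel,
    TrainConfig,
    _sigmoid,
    forward,
    init_weights,
    loss_gradients,
    loss_value,
    mlp_architecture,
    mlp_fit,
    predict,
    slp_fit,
    slp_predict,
)


def two_blobs(n=100, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal([0, 0], 1.0, size=(n, 2))
    b = rng.normal([sep, sep], 1.0, size=(n, 2))
    X = np.vstack([a, b])
    d = np.concatenate([np.zeros(n), np.ones(n)])
    return X, d


def xor_data(reps=40, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    base = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    lab = np.array([0.0, 1.0, 1.0, 0.0])
    X = np.tile(base, (reps, 1)) + noise * rng.standard_normal((4 * reps, 2))
    return X, np.tile(lab, reps)


class TestSLP:
    def test_single_lms_update(self):
        # W=(0,0), X=(1,1), d=1, mu=0.1 -> e=1, feature weights become 0.1
        model = slp_fit(np.array([[1.0, 1.0]]), np.array([[1.0]]),
                        learning_rate=0.1, epochs=1, seed=0)
        assert model.weights[0, 0] == pytest.approx(0.1)
        assert model.weights[1, 0] == pytest.approx(0.1)
        assert model.weights[2, 0] == pytest.approx(0.1)  # bias input is 1

    def test_converges_on_separable_blobs(self):
        X, d = two_blobs(n=100, sep=6.0, seed=1)
        model = slp_fit(X / 10.0, d[:, None], learning_rate=0.1, epochs=50, seed=2)
        scores = slp_predict(model, X / 10.0)[:, 0]
        acc = np.mean((scores >= 0.5) == d)
        assert acc >= 0.99

    def test_fails_on_xor(self):
        X, d = xor_data(seed=3)
        model = slp_fit(X, d[:, None], learning_rate=0.1, epochs=100, seed=4)
        scores = slp_predict(model, X)[:, 0]
        acc = np.mean((scores >= 0.5) == d)
        assert acc <= 0.60

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            slp_fit(np.array([[np.inf, 0.0]]), np.array([[1.0]]))

    def test_deterministic(self):
        X, d = two_blobs(n=30, seed=5)
        m1 = slp_fit(X, d[:, None], epochs=5, seed=9)
        m2 = slp_fit(X, d[:, None], epochs=5, seed=9)
        assert np.array_equal(m1.weights, m2.weights)

    def test_predict_width_mismatch(self):
        model = slp_fit(np.zeros((2, 3)), np.zeros((2, 1)), epochs=1)
        with pytest.raises(ValueError, match="width"):
            slp_predict(model, np.zeros((2, 5)))


class TestArchitectureRule:
    @pytest.mark.parametrize("inp,n_hidden,expected", [
        (4096, 2, [4096, 2048, 1024, 2]),
        (64, 2, [64, 32, 16, 2]),
        (256, 1, [256, 128, 2]),
        (256, 2, [256, 128, 64, 2]),
        (1024, 2, [1024, 512, 256, 2]),
        (64, 1, [64, 32, 2]),
    ])
    def test_halving_rule(self, inp, n_hidden, expected):
        assert mlp_architecture(inp, n_hidden) == expected

    def test_odd_input_needs_override(self):
        with pytest.raises(ValueError, match="halve"):
            mlp_architecture(10, 2)
        assert mlp_architecture(10, 2, allow_odd=True) == [10, 5, 3, 2]

    def test_bad_layer_count(self):
        with pytest.raises(ValueError):
            mlp_architecture(64, 3)


class TestForwardPass:
    def test_zero_weights_give_half(self):
        weights = [np.zeros((5, 4)), np.zeros((5, 2))]
        out = forward(weights, np.random.default_rng(0).random((7, 4)))[-1]
        assert np.allclose(out, 0.5)

    def test_hand_evaluated_2_2_2(self):
        W1 = np.array([[0.3, -0.2], [0.1, 0.4], [0.05, -0.1]])  # last row = bias
        W2 = np.array([[0.7, 0.2], [-0.3, 0.6], [0.1, 0.0]])
        x = np.array([[0.5, -1.0]])
        h = 1 / (1 + np.exp(-(x @ W1[:2] + W1[2])))
        y = 1 / (1 + np.exp(-(h @ W2[:2] + W2[2])))
        out = forward([W1, W2], x)[-1]
        assert np.allclose(out, y, atol=1e-12)

    def test_monotone_in_positive_path_weight(self):
        x = np.array([[1.0]])
        scores = []
        for w in (0.1, 0.5, 2.0):
            weights = [np.array([[w], [0.0]]), np.array([[1.0], [0.0]])]
            scores.append(forward(weights, x)[-1][0, 0])
        assert scores[0] < scores[1] < scores[2]

    def test_sigmoid_stable_for_large_inputs(self):
        z = np.array([-800.0, 800.0])
        s = _sigmoid(z)
        assert s[0] == pytest.approx(0.0, abs=1e-12)
        assert s[1] == pytest.approx(1.0, abs=1e-12)


def numerical_gradients(weights, X, T, loss, eps=1e-5):
    grads = []
    for l, W in enumerate(weights):
        g = np.zeros_like(W)
        for idx in np.ndindex(W.shape):
            orig = W[idx]
            W[idx] = orig + eps
            up = loss_value(weights, X, T, loss)
            W[idx] = orig - eps
            down = loss_value(weights, X, T, loss)
            W[idx] = orig
            g[idx] = (up - down) / (2 * eps)
        grads.append(g)
    return grads


class TestBackpropGradients:
    @pytest.mark.parametrize("loss", ["xent", "mse"])
    @pytest.mark.parametrize("n_hidden", [1, 2])
    def test_analytic_matches_numerical(self, loss, n_hidden):
        rng = np.random.default_rng(11)
        sizes = [6, 4, 2] if n_hidden == 1 else [6, 4, 3, 2]
        weights = [rng.uniform(-0.5, 0.5, (a + 1, b))
                   for a, b in zip(sizes[:-1], sizes[1:])]
        X = rng.random((3, 6))
        T = rng.integers(0, 2, (3, 2)).astype(float)
        analytic = loss_gradients(weights, X, T, loss)
        numeric = numerical_gradients(weights, X, T, loss)
        for a, n in zip(analytic, numeric):
            rel = np.abs(a - n) / np.maximum(1e-8, np.abs(a) + np.abs(n))
            assert rel.max() < 1e-6


class TestMlpFit:
    @pytest.mark.parametrize("optimizer", ["scg", "backprop"])
    def test_solves_xor(self, optimizer):
        wins = 0
        for seed in range(10):
            X, d = xor_data(reps=40, seed=seed)
            Y = np.column_stack([1 - d, d])
            cfg = TrainConfig(optimizer=optimizer, max_epochs=2000,
                              max_validation_fails=2000, seed=seed,
                              learning_rate=0.5)
            model = mlp_fit(X, Y, cfg, layer_sizes=[2, 4, 2])
            pred = np.argmax(predict(model, X), axis=1)
            if np.mean(pred == d) >= 0.99:
                wins += 1
        assert wins >= 8

    def test_zero_epochs_returns_initialized(self):
        rng = np.random.default_rng(0)
        X = rng.random((20, 4))
        Y = np.column_stack([np.ones(20), np.zeros(20)])
        model = mlp_fit(X, Y, TrainConfig(max_epochs=0, seed=1),
                        layer_sizes=[4, 2, 2])
        scores = predict(model, X)
        assert np.all(np.abs(scores - 0.5) < 0.25)
        assert model.trained_epochs == 0

    def test_early_stopping_on_noise_labels(self):
        rng = np.random.default_rng(3)
        X = rng.random((200, 8))
        labels = rng.integers(0, 2, 200).astype(float)
        Y = np.column_stack([1 - labels, labels])
        cfg = TrainConfig(max_epochs=5000, seed=4)
        model = mlp_fit(X, Y, cfg, layer_sizes=[8, 4, 2])
        assert model.stop_reason == "validation_fails"
        assert model.trained_epochs < 5000

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.random((60, 4))
        d = (X[:, 0] > 0.5).astype(float)
        Y = np.column_stack([1 - d, d])
        cfg = TrainConfig(max_epochs=50, seed=7)
        m1 = mlp_fit(X, Y, cfg, layer_sizes=[4, 2, 2])
        m2 = mlp_fit(X, Y, TrainConfig(max_epochs=50, seed=7), layer_sizes=[4, 2, 2])
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)

    def test_records_error_curves(self):
        rng = np.random.default_rng(8)
        X = rng.random((50, 4))
        d = (X[:, 1] > 0.5).astype(float)
        Y = np.column_stack([1 - d, d])
        model = mlp_fit(X, Y, TrainConfig(max_epochs=30, seed=0),
                        layer_sizes=[4, 2, 2])
        assert len(model.train_curve) == len(model.val_curve)
        assert len(model.train_curve) >= 1

    def test_width_mismatch(self):
        X = np.zeros((4, 3))
        Y = np.column_stack([np.ones(4), np.zeros(4)])
        with pytest.raises(ValueError, match="width"):
            mlp_fit(X, Y, TrainConfig(seed=0), layer_sizes=[5, 2, 2])

    def test_y_must_have_two_columns(self):
        with pytest.raises(ValueError, match="two"):
            mlp_fit(np.zeros((4, 2)), np.zeros((4, 3)), TrainConfig())

    def test_predict_width_check(self):
        model = MLPModel(layer_sizes=[4, 2, 2], weights=init_weights([4, 2, 2], 0))
        with pytest.raises(ValueError, match="width"):
            predict(model, np.zeros((3, 6)))
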