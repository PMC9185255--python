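"""MLP initialization, forward pass, backprop gradients, evaluation."""

import numpy as np
import pytest

from pulsecontour import mlp
from pulsecontour.mlp import _forward_pass, _gradients, _loss_value


class TestInitNetwork:
    def test_seeded_determinism(self):
        a = mlp.init_network(10, 3, seed=1)
        b = mlp.init_network(10, 3, seed=1)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_zero_hidden_size_errors(self):
        with pytest.raises(ValueError):
            mlp.init_network(0, 3, seed=1)

    def test_weight_magnitudes_bounded_by_init_scale(self):
        net = mlp.init_network(8, 3, seed=2, input_size=21)
        assert np.abs(net.weights[0]).max() <= 1 / np.sqrt(21)
        assert np.abs(net.weights[1]).max() <= 1 / np.sqrt(8)
        assert all(np.all(b == 0) for b in net.biases)

    def test_default_input_width_is_21(self):
        assert mlp.init_network(8, 3, seed=0).n_inputs == 21


class TestForward:
    def test_zero_weights_logistic_gives_half(self):
        net = mlp.init_network(4, 3, seed=0, input_size=5)
        for w in net.weights:
            w[:] = 0.0
        np.testing.assert_allclose(mlp.forward(net, np.ones(5)), 0.5)

    def test_hand_computed_2_2_1(self):
        """Pencil-and-paper forward pass on fixed weights."""
        net = mlp.init_network(2, 1, seed=0, input_size=2)
        net.weights[0][:] = [[0.5, -0.25], [0.1, 0.3]]
        net.biases[0][:] = [0.0, 0.1]
        net.weights[1][:] = [[0.7], [-0.4]]
        net.biases[1][:] = [0.2]

        def s(z):
            return 1.0 / (1.0 + np.exp(-z))

        h1 = s(0.5 * 1 + 0.1 * 2)
        h2 = s(-0.25 * 1 + 0.3 * 2 + 0.1)
        manual = s(0.7 * h1 - 0.4 * h2 + 0.2)
        assert mlp.forward(net, np.array([1.0, 2.0]))[0] == pytest.approx(
            manual, abs=1e-12
        )

    def test_permuting_identical_hidden_neurons_is_noop(self):
        net = mlp.init_network(2, 1, seed=0, input_size=3)
        net.weights[0][:, 1] = net.weights[0][:, 0]
        net.biases[0][1] = net.biases[0][0]
        net.weights[1][1, 0] = net.weights[1][0, 0]
        x = np.array([0.3, -1.2, 0.5])
        before = mlp.forward(net, x)
        net.weights[0] = net.weights[0][:, ::-1].copy()
        net.weights[1] = net.weights[1][::-1].copy()
        assert mlp.forward(net, x)[0] == pytest.approx(before[0], abs=1e-12)

    def test_wrong_input_length_errors(self):
        net = mlp.init_network(4, 2, seed=0)
        with pytest.raises(ValueError, match="21"):
            mlp.forward(net, np.ones(5))

    def test_scores_in_unit_interval(self):
        net = mlp.init_network(8, 3, seed=3)
        scores = mlp.forward(net, np.random.default_rng(0).normal(size=21) * 10)
        assert np.all((scores > 0) & (scores < 1))


@pytest.mark.parametrize("activation", ["logistic", "tanh"])
@pytest.mark.parametrize("loss", ["sse", "cross_entropy"])
def test_backprop_gradient_matches_finite_differences(activation, loss):
    """Analytic gradients agree with central differences to 1e-6 relative
    on a random 21-8-3 network, for every activation/loss choice."""
    rng = np.random.default_rng(0)
    net = mlp.init_network(8, 3, seed=2, input_size=21, activation=activation)
    X = rng.normal(size=(6, 21))
    Y = np.eye(3)[rng.integers(0, 3, 6)]
    gW, gb, _ = _gradients(net, X, Y, loss)
    h = 1e-6
    for layer in range(2):
        for arr, grad in ((net.weights[layer], gW[layer]),
                          (net.biases[layer], gb[layer])):
            flat = arr.reshape(-1)
            for j in rng.choice(flat.size, size=min(20, flat.size), replace=False):
                orig = flat[j]
                flat[j] = orig + h
                lp = _loss_value(Y, _forward_pass(net, X)[-1], loss)
                flat[j] = orig - h
                lm = _loss_value(Y, _forward_pass(net, X)[-1], loss)
                flat[j] = orig
                fd = (lp - lm) / (2 * h)
                g = grad.reshape(-1)[j]
                assert abs(fd - g) <= 1e-6 * max(1.0, abs(fd))


class TestTrainBackprop:
    def test_xor_converges(self):
        """4-point XOR with 4 hidden neurons: loss < 0.05 within 5000 epochs."""
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        y = [0, 1, 1, 0]
        net = mlp.init_network(4, 1, seed=1, input_size=2)
        net, trace = mlp.train_backprop(
            net, X, y,
            mlp.TrainConfig(learning_rate=2.0, epochs=5000, shuffle_seed=1),
            standardize=False,
        )
        assert trace[-1] < 0.05

    def test_zero_learning_rate_rejected(self):
        with pytest.raises(ValueError):
            mlp.TrainConfig(learning_rate=0.0)

    def test_tiny_learning_rate_leaves_weights_nearly_unchanged(self):
        X = np.array([[0, 0], [1, 1]], float)
        net = mlp.init_network(2, 1, seed=0, input_size=2)
        w0 = [w.copy() for w in net.weights]
        net, _ = mlp.train_backprop(
            net, X, [0, 1],
            mlp.TrainConfig(learning_rate=1e-12, epochs=1), standardize=False,
        )
        for w, w_orig in zip(net.weights, w0):
            np.testing.assert_allclose(w, w_orig, atol=1e-10)

    def test_single_class_data_errors(self):
        X = np.zeros((4, 21))
        net = mlp.init_network(4, 2, seed=0)
        with pytest.raises(ValueError, match="2 classes"):
            mlp.train_backprop(net, X, ["a"] * 4)

    def test_full_batch_descent_never_increases_loss(self):
        """Full-batch descent on XOR with a small rate is monotone."""
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        net = mlp.init_network(4, 1, seed=1, input_size=2)
        net, trace = mlp.train_backprop(
            net, X, [0, 1, 1, 0],
            mlp.TrainConfig(learning_rate=1e-3, epochs=400,
                            batch_mode="full-batch"),
            standardize=False,
        )
        assert np.all(np.diff(trace) <= 1e-12)

    def test_reproducible_from_seeds(self):
        X = np.random.default_rng(3).normal(size=(20, 21))
        y = ["a", "b"] * 10
        runs = []
        for _ in range(2):
            net = mlp.init_network(5, 2, seed=4)
            net, trace = mlp.train_backprop(
                net, X, y, mlp.TrainConfig(epochs=20, shuffle_seed=4))
            runs.append(trace)
        np.testing.assert_array_equal(runs[0], runs[1])


class TestEvaluate:
    def test_toy_confusion_arithmetic(self):
        """TP 8, FN 2, FP 1, TN 9 gives sensitivity 0.8, specificity 0.9."""
        sens, spec = mlp.confusion_rates(tp=8, fn=2, fp=1, tn=9)
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(0.9)

    def test_perfect_predictions(self):
        net = mlp.init_network(4, 2, seed=0, input_size=2)
        X = np.array([[0.0, 0], [0, 0], [9, 9], [9, 9]])
        net, _ = mlp.train_backprop(
            net, X, ["a", "a", "b", "b"],
            mlp.TrainConfig(learning_rate=1.0, epochs=500, shuffle_seed=0),
        )
        res = mlp.evaluate(net, X, ["a", "a", "b", "b"])
        assert res.accuracy == 1.0
        assert all(v == 1.0 for v in res.sensitivity.values())
        assert all(v == 1.0 for v in res.specificity.values())

    def test_confusion_rows_sum_to_class_counts(self, two_class_cohort):
        from pulsecontour.features import FEATURE_VECTOR_NAMES
        _, table = two_class_cohort
        X = table[list(FEATURE_VECTOR_NAMES)].to_numpy(float)
        y = table.label.tolist()
        net = mlp.init_network(4, 2, seed=0)
        net, _ = mlp.train_backprop(net, X, y, mlp.TrainConfig(epochs=50))
        res = mlp.evaluate(net, X, y)
        counts = {c: y.count(c) for c in res.classes}
        for i, c in enumerate(res.classes):
            assert res.confusion[i].sum() == counts[c]
        assert res.confusion.sum() == len(y)

    def test_empty_data_errors(self):
        net = mlp.init_network(4, 2, seed=0)
        net.classes = ("a", "b")
        with pytest.raises(ValueError, match="empty"):
            mlp.evaluate(net, np.zeros((0, 21)), [])


class TestSelectHiddenSize:
    def _data(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0, 1, (30, 21)),
                            rng.normal(4, 1, (30, 21))])
        y = ["a"] * 30 + ["b"] * 30
        return X, y

    def test_table_schema(self):
        X, y = self._data()
        cfg = mlp.TrainConfig(epochs=30)
        table = mlp.select_hidden_size(X, y, [2, 8], cfg, n_folds=3, seed=1)
        assert set(table.hidden_size) == {2, 8}
        assert set(table.output_class) == {"a", "b"}
        assert ((table.sensitivity >= 0) & (table.sensitivity <= 1)).all()
        assert ((table.specificity >= 0) & (table.specificity <= 1)).all()

    def test_deterministic_given_seeds(self):
        X, y = self._data()
        cfg = mlp.TrainConfig(epochs=20)
        t1 = mlp.select_hidden_size(X, y, [2, 4], cfg, n_folds=3, seed=1)
        t2 = mlp.select_hidden_size(X, y, [2, 4], cfg, n_folds=3, seed=1)
        assert t1.equals(t2)

    def test_needs_two_candidates(self):
        X, y = self._data()
        with pytest.raises(ValueError):
            mlp.select_hidden_size(X, y, [4], mlp.TrainConfig())


class TestPersistence:
    def test_json_roundtrip(self, tmp_path):
        net = mlp.init_network(6, 2, seed=9)
        X = np.random.default_rng(1).normal(size=(10, 21))
        net, _ = mlp.train_backprop(net, X, ["a", "b"] * 5,
                                    mlp.TrainConfig(epochs=5))
        p = tmp_path / "model.json"
        mlp.save_model(net, p)
        back = mlp.load_model(p)
        x = np.random.default_rng(2).normal(size=21)
        np.testing.assert_allclose(mlp.forward(back, x), mlp.forward(net, x),
                                   atol=1e-12)
        assert back.classes == net.classes
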