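import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contactcascade import neural_net as nn
from contactcascade.synthetic_data import separable_dataset


class TestInitNetwork:
    def test_seeded_determinism(self):
        a = nn.init_network((1747, 5, 1), seed=42)
        b = nn.init_network((1747, 5, 1), seed=42)
        for k in ("w1", "b1", "w2", "b2"):
            np.testing.assert_array_equal(getattr(a, k), getattr(b, k))

    @pytest.mark.parametrize("sizes,count", [((9, 6, 1), 67), ((1747, 5, 1), 8746)])
    def test_parameter_counts(self, sizes, count):
        assert nn.init_network(sizes, seed=0).n_parameters == count

    def test_bad_architecture(self):
        with pytest.raises(nn.NetworkError, match="bad architecture"):
            nn.init_network((3, 0, 1), seed=0)


class TestForward:
    def test_zero_weights_give_half(self):
        m = nn.init_network((4, 3, 1), seed=0)
        for k in ("w1", "b1", "w2", "b2"):
            setattr(m, k, np.zeros_like(getattr(m, k)))
        assert nn.forward(m, np.ones(4)) == pytest.approx(0.5)

    def test_hand_computed_forward_pass(self):
        m = nn.init_network((2, 2, 1), seed=0)
        m.w1 = np.array([[0.1, -0.2], [0.3, 0.4]])
        m.b1 = np.array([0.05, -0.05])
        m.w2 = np.array([[0.2, -0.1]])
        m.b2 = np.array([0.15])
        x = np.array([1.0, 2.0])

        def sig(v):
            return 1.0 / (1.0 + math.exp(-v))

        h1 = sig(0.1 * 1.0 - 0.2 * 2.0 + 0.05)
        h2 = sig(0.3 * 1.0 + 0.4 * 2.0 - 0.05)
        expect = sig(0.2 * h1 - 0.1 * h2 + 0.15)
        assert nn.forward(m, x) == pytest.approx(expect, abs=1e-12)

    def test_output_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(1)
        m = nn.init_network((6, 4, 1), seed=1)
        out = nn.forward(m, rng.normal(scale=50, size=(20, 6)))
        assert np.all(out > 0) and np.all(out < 1)

    def test_width_mismatch(self):
        m = nn.init_network((4, 2, 1), seed=0)
        with pytest.raises(nn.NetworkError, match="bad input width"):
            nn.forward(m, np.ones(5))


class TestGradients:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_backprop_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        sizes = (int(rng.integers(2, 6)), int(rng.integers(2, 5)), 1)
        m = nn.init_network(sizes, seed=seed)
        x = rng.normal(size=(5, sizes[0]))
        y = rng.integers(0, 2, size=5).astype(float)
        _, grads = nn.loss_and_gradients(m, x, y)
        eps = 1e-6
        for key in ("w1", "b1", "w2", "b2"):
            w = getattr(m, key)
            it = np.nditer(w, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                w[idx] += eps
                lp, _ = nn.loss_and_gradients(m, x, y)
                w[idx] -= 2 * eps
                lm, _ = nn.loss_and_gradients(m, x, y)
                w[idx] += eps
                numeric = (lp - lm) / (2 * eps)
                assert abs(numeric - grads[key][idx]) < 1e-6


class TestBalancedSample:
    def test_minority_class_kept_whole(self):
        labels = [1] * 10 + [0] * 100
        sel = nn.balanced_sample(labels, factor=1.0, seed=0)
        picked = np.asarray(labels)[sel]
        assert (picked == 1).sum() == 10
        assert (picked == 0).sum() == 10

    def test_balanced_input_is_identity_up_to_order(self):
        labels = [1] * 5 + [0] * 5
        sel = nn.balanced_sample(labels, factor=1.0, seed=1)
        assert sorted(sel) == list(range(10))

    def test_factor_thinning_keeps_classes_equal_and_reproducible(self):
        labels = [1] * 40 + [0] * 200
        a = nn.balanced_sample(labels, factor=0.5, seed=7)
        b = nn.balanced_sample(labels, factor=0.5, seed=7)
        np.testing.assert_array_equal(a, b)
        picked = np.asarray(labels)[a]
        assert (picked == 1).sum() == (picked == 0).sum()
        assert (picked == 1).sum() < 40  # thinned below the full positive count

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_exact_balance_property(self, n_pos, n_neg, seed):
        labels = [1] * n_pos + [0] * n_neg
        picked = np.asarray(labels)[nn.balanced_sample(labels, 1.0, seed)]
        assert (picked == 1).sum() == (picked == 0).sum() == min(n_pos, n_neg)

    def test_absent_class_raises(self):
        with pytest.raises(nn.NetworkError, match="cannot balance"):
            nn.balanced_sample([1, 1, 1], factor=1.0, seed=0)


class TestTrain:
    def test_learns_separable_encodings(self):
        x, y = separable_dataset(200, seed=0)
        m = nn.init_network((1747, 5, 1), seed=0)
        m, _ = nn.train(m, x, y, nn.TrainConfig(seed=0))
        acc = ((nn.forward(m, x) >= 0.5) == y.astype(bool)).mean()
        assert acc >= 0.95

    def test_single_repeated_positive_monotone(self):
        x = np.tile(np.array([1.0, -1.0, 0.5]), (4, 1))
        y = np.ones(4)
        m = nn.init_network((3, 2, 1), seed=0)
        cfg = nn.TrainConfig(max_epochs=100, validation_fraction=0.0,
                             patience=0, seed=0)
        m2, history = nn.train(m, x, y, cfg)
        assert history == sorted(history, reverse=True)  # loss falls monotonically
        assert nn.forward(m2, x[0]) > nn.forward(m, x[0])

    def test_loss_non_increasing_small_lr_full_batch(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 4))
        y = (x[:, 0] > 0).astype(float)
        m = nn.init_network((4, 3, 1), seed=0)
        cfg = nn.TrainConfig(learning_rate=1e-3, momentum=0.0, max_epochs=50,
                             validation_fraction=0.0, patience=0, seed=0)
        _, history = nn.train(m, x, y, cfg)
        assert all(a >= b - 1e-12 for a, b in zip(history, history[1:]))

    def test_seeded_training_bit_reproducible(self):
        x, y = separable_dataset(64, seed=3)
        cfg = nn.TrainConfig(max_epochs=30, seed=5)
        m1, h1 = nn.train(nn.init_network((1747, 4, 1), seed=5), x, y, cfg)
        m2, h2 = nn.train(nn.init_network((1747, 4, 1), seed=5), x, y, cfg)
        assert h1 == h2
        for k in ("w1", "b1", "w2", "b2"):
            np.testing.assert_array_equal(getattr(m1, k), getattr(m2, k))

    def test_empty_data_raises(self):
        m = nn.init_network((3, 2, 1), seed=0)
        with pytest.raises(nn.NetworkError, match="no samples"):
            nn.train(m, np.empty((0, 3)), np.empty(0), nn.TrainConfig())


def test_model_json_round_trip():
    m = nn.init_network((5, 3, 1), seed=9)
    m.threshold = 0.7
    m.trained = True
    m2 = nn.NetworkModel.from_json(m.to_json())
    assert m2.layer_sizes == m.layer_sizes
    assert m2.threshold == 0.7 and m2.trained
    for k in ("w1", "b1", "w2", "b2"):
        np.testing.assert_array_equal(getattr(m, k), getattr(m2, k))
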