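"""LSTM gate equations, encoder contracts, and branch training."""

import numpy as np
import pytest

import boldfusion as bf
from boldfusion.lstm import (
    STAGE2_PRESET,
    LstmLayerParams,
    LstmState,
    init_lstm_params,
)


def reference_cell_step(x, h_prev, c_prev, layer):
    """Straight-from-the-gate-equations oracle, elementwise loops only."""

    def sigmoid(v):
        return 1.0 / (1.0 + np.exp(-v))

    z = np.concatenate([h_prev, x])
    h_out = np.empty_like(h_prev)
    c_out = np.empty_like(c_prev)
    for u in range(len(h_prev)):
        i = sigmoid(float(layer.W_i[u] @ z) + layer.b_i[u])
        f = sigmoid(float(layer.W_f[u] @ z) + layer.b_f[u])
        o = sigmoid(float(layer.W_o[u] @ z) + layer.b_o[u])
        g = np.tanh(float(layer.W_c[u] @ z) + layer.b_c[u])
        c_out[u] = i * g + f * c_prev[u]
        h_out[u] = o * np.tanh(c_out[u])
    return h_out, c_out


class TestCellStep:
    def test_hand_evaluated_scalar_case(self):
        # scalar unit, all weights 0.5, zero biases and state, x = 1
        layer = LstmLayerParams(np.full((4, 2), 0.5), np.zeros(4))
        state = bf.lstm_cell_step(
            np.array([1.0]), LstmState(np.zeros(1), np.zeros(1)), layer
        )
        sig = 1.0 / (1.0 + np.exp(-0.5))
        c_expected = sig * np.tanh(0.5)
        h_expected = sig * np.tanh(c_expected)
        assert state.c[0] == pytest.approx(c_expected, abs=1e-10)
        assert state.h[0] == pytest.approx(h_expected, abs=1e-10)

    def test_zero_parameters_keep_zero_state(self):
        layer = LstmLayerParams(np.zeros((4, 3)), np.zeros(4))
        state = bf.lstm_cell_step(
            np.array([3.0, -2.0]), LstmState(np.zeros(1), np.zeros(1)), layer
        )
        assert state.h[0] == 0.0 and state.c[0] == 0.0

    def test_saturated_forget_gate_preserves_memory_exactly(self, rng):
        h = 2
        layer = init_lstm_params(1, (h,), seed=0).layers[0]
        b = layer.b.copy()
        b[:h] = -1000.0  # input gate -> 0
        b[h : 2 * h] = 1000.0  # forget gate -> 1
        layer = LstmLayerParams(layer.W, b)
        c_prev = rng.normal(size=h)
        state = bf.lstm_cell_step(
            np.array([0.7]), LstmState(np.zeros(h), c_prev), layer
        )
        np.testing.assert_array_equal(state.c, c_prev)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_equation_oracle_on_random_cases(self, seed):
        r = np.random.default_rng(seed)
        h, d = int(r.integers(1, 6)), int(r.integers(1, 4))
        layer = LstmLayerParams(r.normal(size=(4 * h, h + d)), r.normal(size=4 * h))
        x = r.normal(size=d)
        h_prev, c_prev = r.normal(size=h), r.normal(size=h)
        state = bf.lstm_cell_step(x, LstmState(h_prev, c_prev), layer)
        h_ref, c_ref = reference_cell_step(x, h_prev, c_prev, layer)
        np.testing.assert_allclose(state.h, h_ref, atol=1e-10)
        np.testing.assert_allclose(state.c, c_ref, atol=1e-10)
        assert np.all(np.abs(state.h) < 1.0)  # |h| = |o * tanh(c)| < 1

    def test_shape_mismatch_rejected(self):
        layer = LstmLayerParams(np.zeros((4, 3)), np.zeros(4))
        with pytest.raises(ValueError, match="mismatch"):
            bf.lstm_cell_step(
                np.array([1.0, 2.0, 3.0]), LstmState(np.zeros(1), np.zeros(1)), layer
            )


class TestEncode:
    def test_stage1_preset_yields_100_features(self, rng):
        params = init_lstm_params(1, (150, 100), seed=0)
        out = bf.lstm_encode(rng.normal(size=600), params)
        assert out.shape == (100,)
        batch = bf.lstm_encode(rng.normal(size=(3, 600)), params)
        assert batch.shape == (3, 100)

    def test_zero_parameters_encode_to_zero(self, rng):
        params = init_lstm_params(1, (8, 4), seed=0, scale=0.0)
        np.testing.assert_array_equal(
            bf.lstm_encode(rng.normal(size=50), params), np.zeros(4)
        )

    def test_encoding_is_deterministic(self, rng):
        params = init_lstm_params(1, (16, 8), seed=3)
        x = rng.normal(size=(2, 120))
        np.testing.assert_array_equal(
            bf.lstm_encode(x, params), bf.lstm_encode(x, params)
        )


class TestTraining:
    def test_loss_decreases_on_a_learnable_pool(self, rng):
        n = 40
        t = np.arange(80)
        X = np.stack(
            [np.sin(2 * np.pi * (3 if i % 2 else 7) * t / 80) for i in range(n)]
        ) + 0.1 * rng.normal(size=(n, 80))
        y = np.arange(n) % 2
        params = bf.train_lstm_branch(
            X, y, hidden_sizes=(12, 8), epochs=5, batch_size=20, seed=0
        )
        assert params.loss_history_[-1] < params.loss_history_[0]

    def test_training_is_seed_deterministic(self, rng):
        X = rng.normal(size=(16, 40))
        y = np.arange(16) % 2
        a = bf.train_lstm_branch(X, y, hidden_sizes=(6, 4), epochs=2, seed=9)
        b = bf.train_lstm_branch(X, y, hidden_sizes=(6, 4), epochs=2, seed=9)
        for la, lb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(la.W, lb.W)
            np.testing.assert_array_equal(la.b, lb.b)

    def test_stage2_preset_instantiates_150_100_with_dropout(self, rng):
        X = rng.normal(size=(12, 30))
        y = np.arange(12) % 2
        params = bf.train_lstm_branch(
            X, y, hidden_sizes=STAGE2_PRESET["hidden_sizes"],
            dropout=STAGE2_PRESET["dropout"], epochs=1, seed=0,
        )
        assert params.hidden_sizes == (150, 100)
        assert params.dropout == (0.2, 0.1)
        assert params.layers[0].W.shape == (600, 151)
        assert params.layers[1].W.shape == (400, 250)

    def test_degenerate_pools_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            bf.train_lstm_branch(np.empty((0, 10)), np.empty(0))
        with pytest.raises(ValueError, match="2 classes"):
            bf.train_lstm_branch(rng.normal(size=(5, 10)), np.zeros(5))
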