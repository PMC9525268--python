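"""LSTM gate equations, gradients, and training contracts.

The cell is checked against an independent scalar evaluation of the gate
equations written in plain ``math`` arithmetic, and the backward pass
against central finite differences.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slepredict.evaluation import auc_mann_whitney
from slepredict.lstm import (
    LSTMClassifier,
    LSTMParams,
    TrainConfig,
    init_params,
    loss_and_gradients,
    lstm_cell,
    lstm_forward,
    train_lstm,
    _dict_to_params,
    _params_to_dict,
)


# --- independent scalar oracle (hidden_size = input_dim = 1) ---------------

def scalar_lstm_step(w, x, h, c):
    """Longhand evaluation of the gate equations for scalar weights.

    ``w`` maps gate name -> (w_h, w_x, b).
    """
    sig = lambda z: 1.0 / (1.0 + math.exp(-z))
    i = sig(w["i"][0] * h + w["i"][1] * x + w["i"][2])
    f = sig(w["f"][0] * h + w["f"][1] * x + w["f"][2])
    o = sig(w["o"][0] * h + w["o"][1] * x + w["o"][2])
    g = math.tanh(w["c"][0] * h + w["c"][1] * x + w["c"][2])
    c_new = f * c + i * g
    h_new = o * math.tanh(c_new)
    return h_new, c_new


def _scalar_params(w, w_out=1.0, b_out=0.0) -> LSTMParams:
    return LSTMParams(
        W_i=np.array([[w["i"][0], w["i"][1]]]),
        W_f=np.array([[w["f"][0], w["f"][1]]]),
        W_o=np.array([[w["o"][0], w["o"][1]]]),
        W_c=np.array([[w["c"][0], w["c"][1]]]),
        b_i=np.array([w["i"][2]]),
        b_f=np.array([w["f"][2]]),
        b_o=np.array([w["o"][2]]),
        b_c=np.array([w["c"][2]]),
        w_out=np.array([w_out]),
        b_out=b_out,
    )


SCALAR_WEIGHTS = {
    "i": (0.3, -0.5, 0.1),
    "f": (-0.2, 0.4, 0.7),
    "o": (0.6, 0.2, -0.3),
    "c": (0.5, 0.9, 0.05),
}

# 12 (x, h, c) evaluation points spanning sign/magnitude combinations
SCALAR_POINTS = [
    (0.0, 0.0, 0.0),
    (1.0, 0.0, 0.0),
    (-1.0, 0.5, 0.2),
    (0.5, -0.5, 1.0),
    (2.0, 0.3, -0.7),
    (-2.0, -0.3, 0.7),
    (0.1, 0.9, -1.5),
    (3.0, -1.0, 2.0),
    (-0.7, 0.2, 0.4),
    (1.5, 1.5, 1.5),
    (-1.5, -1.5, -1.5),
    (0.25, 0.75, -0.25),
]


class TestLSTMCell:
    def test_zero_weights_closed_form(self):
        zero = {g: (0.0, 0.0, 0.0) for g in "ifoc"}
        params = _scalar_params(zero)
        for c_prev in (-2.0, 0.0, 1.3):
            h, c = lstm_cell(params, np.array([4.2]), np.array([0.0]), np.array([c_prev]))
            assert c[0] == pytest.approx(0.5 * c_prev, abs=1e-12)
            assert h[0] == pytest.approx(0.5 * math.tanh(0.5 * c_prev), abs=1e-12)

    @pytest.mark.parametrize("x,h,c", SCALAR_POINTS)
    def test_matches_scalar_oracle(self, x, h, c):
        params = _scalar_params(SCALAR_WEIGHTS)
        h_new, c_new = lstm_cell(params, np.array([x]), np.array([h]), np.array([c]))
        h_ref, c_ref = scalar_lstm_step(SCALAR_WEIGHTS, x, h, c)
        assert abs(h_new[0] - h_ref) < 1e-10
        assert abs(c_new[0] - c_ref) < 1e-10

    def test_batch_consistent_with_single(self):
        rng = np.random.default_rng(0)
        params = init_params(4, 3, rng)
        X = rng.normal(size=(5, 4))
        h0 = rng.normal(size=(5, 3))
        c0 = rng.normal(size=(5, 3))
        hb, cb = lstm_cell(params, X, h0, c0)
        for i in range(5):
            hi, ci = lstm_cell(params, X[i], h0[i], c0[i])
            np.testing.assert_allclose(hb[i], hi, atol=1e-12)
            np.testing.assert_allclose(cb[i], ci, atol=1e-12)

    def test_shape_mismatch_raises(self):
        params = init_params(4, 3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            lstm_cell(params, np.zeros(5), np.zeros(3), np.zeros(3))

    @given(
        x=st.floats(-50, 50),
        h=st.floats(-1, 1),
        c=st.floats(-20, 20),
    )
    @settings(max_examples=100, derandomize=True)
    def test_gates_strictly_inside_unit_interval(self, x, h, c):
        w = SCALAR_WEIGHTS
        sig = lambda z: 1.0 / (1.0 + math.exp(-z))
        for gate in "ifo":
            val = sig(w[gate][0] * h + w[gate][1] * x + w[gate][2])
            assert 0.0 < val < 1.0
        params = _scalar_params(w)
        h_new, _ = lstm_cell(params, np.array([x]), np.array([h]), np.array([c]))
        assert -1.0 < h_new[0] < 1.0


class TestLSTMForward:
    def test_zero_weights_probability_half(self):
        zero = {g: (0.0, 0.0, 0.0) for g in "ifoc"}
        params = _scalar_params(zero, w_out=0.0, b_out=0.0)
        seq = np.random.default_rng(1).normal(size=(4, 1))
        assert lstm_forward(params, seq) == pytest.approx(0.5)

    def test_single_step_identity(self):
        params = _scalar_params(SCALAR_WEIGHTS, w_out=2.0, b_out=-0.5)
        x = 0.8
        h, _ = scalar_lstm_step(SCALAR_WEIGHTS, x, 0.0, 0.0)
        expected = 1.0 / (1.0 + math.exp(-(2.0 * h - 0.5)))
        assert lstm_forward(params, np.array([[x]])) == pytest.approx(expected, abs=1e-12)

    def test_two_step_chain_matches_oracle(self):
        params = _scalar_params(SCALAR_WEIGHTS, w_out=1.5, b_out=0.2)
        h, c = 0.0, 0.0
        for x in (0.4, -1.1):
            h, c = scalar_lstm_step(SCALAR_WEIGHTS, x, h, c)
        expected = 1.0 / (1.0 + math.exp(-(1.5 * h + 0.2)))
        got = lstm_forward(params, np.array([[0.4], [-1.1]]))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_empty_sequence_raises(self):
        params = init_params(2, 3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            lstm_forward(params, np.zeros((0, 2)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        params = init_params(2, 3, rng)
        theta = _params_to_dict(params)
        X = rng.normal(size=(4, 3, 2))
        y = np.array([0.0, 1.0, 1.0, 0.0])
        _, grads = loss_and_gradients(theta, X, y)
        eps = 1e-6
        for key in theta:
            num = np.zeros_like(theta[key])
            it = np.nditer(theta[key], flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                for sign in (+1, -1):
                    theta[key][idx] += sign * eps
                    loss, _ = loss_and_gradients(theta, X, y)
                    num[idx] += sign * loss / (2 * eps)
                    theta[key][idx] -= sign * eps
            np.testing.assert_allclose(grads[key], num, rtol=1e-5, atol=1e-8)


def _toy_sequences(n, k, rng, separation=1.0):
    """Upward- vs downward-trending 1-feature sequences."""
    y = rng.integers(0, 2, n)
    t = np.arange(k)
    X = np.empty((n, k, 1))
    for i in range(n):
        slope = separation if y[i] == 1 else -separation
        X[i, :, 0] = slope * t + rng.normal(0, 0.3, k)
    return X, y


class TestTraining:
    def test_loss_decreases_and_learns_separable_task(self):
        rng = np.random.default_rng(0)
        X, y = _toy_sequences(240, 4, rng)
        cfg = TrainConfig(epochs=60, batch_size=32, learning_rate=0.05, seed=0)
        params, losses = train_lstm(X[:160], y[:160], hidden_size=4, config=cfg)
        assert losses[-1] <= losses[0]
        pred = (lstm_forward(params, X[160:]) >= 0.5).astype(int)
        assert (pred == y[160:]).mean() >= 0.95

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(3)
        X, y = _toy_sequences(2500, 2, rng)
        y_shuffled = rng.permutation(y)
        cfg = TrainConfig(epochs=10, batch_size=128, learning_rate=0.02, seed=1)
        params, _ = train_lstm(X[:2000], y_shuffled[:2000], hidden_size=4, config=cfg)
        auc = auc_mann_whitney(y_shuffled[2000:], lstm_forward(params, X[2000:]))
        assert 0.4 <= auc <= 0.6

    def test_same_seed_identical_parameters(self):
        rng = np.random.default_rng(2)
        X, y = _toy_sequences(60, 3, rng)
        cfg = TrainConfig(epochs=5, batch_size=16, learning_rate=0.01, seed=7)
        p1, _ = train_lstm(X, y, hidden_size=3, config=cfg)
        p2, _ = train_lstm(X, y, hidden_size=3, config=cfg)
        np.testing.assert_array_equal(p1.W_i, p2.W_i)
        np.testing.assert_array_equal(p1.w_out, p2.w_out)

    def test_non_finite_loss_aborts_with_diagnostic(self):
        rng = np.random.default_rng(4)
        X, y = _toy_sequences(64, 2, rng)
        X[5, 1, 0] = np.nan  # corrupt input propagates to a NaN loss
        cfg = TrainConfig(epochs=3, batch_size=64, learning_rate=0.01, seed=0)
        with pytest.raises(RuntimeError, match="non-finite"):
            train_lstm(X, y, hidden_size=2, config=cfg)

    def test_single_class_labels_raise(self):
        with pytest.raises(ValueError):
            train_lstm(np.zeros((10, 2, 1)), np.zeros(10), hidden_size=2)


class TestLSTMClassifier:
    def test_fit_predict_on_separable_task(self):
        rng = np.random.default_rng(6)
        X, y = _toy_sequences(240, 4, rng)
        clf = LSTMClassifier(
            hidden_size=4, epochs=60, batch_size=32, learning_rate=0.05, random_state=0
        )
        clf.fit(X[:160], y[:160])
        assert (clf.predict(X[160:]) == y[160:]).mean() >= 0.95
        proba = clf.predict_proba(X[160:])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_oversample_indices_recorded(self):
        rng = np.random.default_rng(7)
        X, y = _toy_sequences(100, 2, rng)
        y = (np.arange(100) < 10).astype(int)  # 10 vs 90 imbalance
        clf = LSTMClassifier(hidden_size=2, epochs=2, learning_rate=0.01, random_state=0)
        clf.fit(X, y)
        counts = np.bincount(clf.oversample_indices_, minlength=100)
        assert set(counts[:10]) == {9}  # r = round(90/10) = 9
        assert set(counts[10:]) == {1}

    def test_requires_3d_input(self):
        clf = LSTMClassifier()
        with pytest.raises(ValueError, match="3-D"):
            clf.fit(np.zeros((10, 4)), np.zeros(10))

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        clf = LSTMClassifier(hidden_size=8, epochs=3, random_state=1)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()


class TestCheckpoint:
    def test_saved_params_reload_to_identical_outputs(self, tmp_path):
        from slepredict.lstm import load_params, save_params

        rng = np.random.default_rng(8)
        params = init_params(3, 4, rng)
        path = tmp_path / "lstm.npz"
        save_params(params, path)
        back = load_params(path)
        seq = rng.normal(size=(6, 5, 3))
        np.testing.assert_array_equal(lstm_forward(params, seq), lstm_forward(back, seq))
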