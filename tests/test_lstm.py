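"""LSTM cell/sequence correctness against an independent per-equation oracle,
gradient checks, and training behaviour on a constructed identifiable task."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grfest import (LSTMParams, LSTMState, TrainConfig, SequenceDataset,
                    forward_sequence, init_params, loss_and_grads,
                    lstm_cell_forward, finite_difference_check,
                    mean_predictor_baseline, predict_wrench, train_model,
                    percent_rmse, get_pattern)
from grfest.dataset import ChannelStats
from grfest.errors import ModelError


# ---------------------------------------------------------------------------
# independent oracle: the four gate equations coded step by step, scalar-wise
# ---------------------------------------------------------------------------

def _sig(z):
    return 1.0 / (1.0 + np.exp(-z))


def oracle_sequence(X, p: LSTMParams):
    """Plain per-equation recurrence, written independently of the package."""
    H = p.bf.shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    hs = []
    for x in X:
        f = _sig(x @ p.Wxf + h @ p.Whf + p.bf)
        if p.g_gate == "sigmoid_as_printed":
            g = _sig(x @ p.Wxg + h @ p.Whg + p.bg)
        else:
            g = np.tanh(x @ p.Wxg + h @ p.Whg + p.bg)
        i = _sig(x @ p.Wxi + h @ p.Whi + p.bi)
        o = _sig(x @ p.Wxo + h @ p.Who + p.bo)
        c = f * c + g * i
        h = o * np.tanh(c)
        hs.append(h.copy())
    hs = np.stack(hs)
    return hs, hs @ p.Wout + p.bout


def random_params(rng, d, H, g_gate="sigmoid_as_printed"):
    p = init_params(d, H, seed=int(rng.integers(2 ** 31)), g_gate=g_gate)
    # scramble biases too so nothing stays at its structured init
    p.bf = rng.normal(size=H)
    p.bg = rng.normal(size=H)
    p.bi = rng.normal(size=H)
    p.bo = rng.normal(size=H)
    return p


class TestCellForward:
    def test_all_zero_parameters_force_known_state(self):
        """sigma(0)=0.5 everywhere: c1 = 0.25, h1 = 0.5*tanh(0.25)."""
        d, H = 3, 5
        p = init_params(d, H, seed=0)
        for k in ("Wxf", "Wxg", "Wxi", "Wxo", "Whf", "Whg", "Whi", "Who",
                  "Wout"):
            setattr(p, k, np.zeros_like(getattr(p, k)))
        for k in ("bf", "bg", "bi", "bo", "bout"):
            setattr(p, k, np.zeros_like(getattr(p, k)))
        s1 = lstm_cell_forward(np.ones(d), LSTMState.zeros(H), p)
        assert np.allclose(s1.c, 0.25)
        assert np.allclose(s1.h, 0.5 * np.tanh(0.25))

    def test_memory_retention_limit(self):
        """f ~= 1 and i ~= 0 freeze the cell state."""
        d, H = 2, 4
        p = init_params(d, H, seed=1)
        p.bf = np.full(H, 50.0)    # forget gate saturated open
        p.bi = np.full(H, -50.0)   # input gate closed
        state = LSTMState(h=np.zeros(H), c=np.array([0.3, -0.2, 1.0, 0.0]))
        rng = np.random.default_rng(2)
        for _ in range(5):
            state = lstm_cell_forward(rng.standard_normal(d), state, p)
        assert np.allclose(state.c, [0.3, -0.2, 1.0, 0.0], atol=1e-12)

    def test_dimension_mismatch_raises(self):
        p = init_params(3, 4, seed=0)
        with pytest.raises(ModelError):
            lstm_cell_forward(np.ones(5), LSTMState.zeros(4), p)


class TestOracleEquivalence:
    @pytest.mark.parametrize("g_gate", ["sigmoid_as_printed", "tanh_standard"])
    def test_forward_matches_independent_recurrence(self, g_gate):
        """100 random small instances agree with the oracle to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            d = int(rng.integers(1, 5))
            H = int(rng.integers(1, 9))
            T = int(rng.integers(1, 11))
            p = random_params(rng, d, H, g_gate)
            X = rng.standard_normal((T, d))
            _, y_oracle = oracle_sequence(X, p)
            y = forward_sequence(X, p)
            assert np.max(np.abs(y - y_oracle)) < 1e-10
            # stepwise cell API agrees too
            state = LSTMState.zeros(H)
            for t in range(T):
                state = lstm_cell_forward(X[t], state, p)
            hs, _ = oracle_sequence(X, p)
            assert np.max(np.abs(state.h - hs[-1])) < 1e-10

    def test_single_frame_equals_head_of_first_step(self):
        rng = np.random.default_rng(3)
        p = random_params(rng, 3, 6)
        x = rng.standard_normal((1, 3))
        y = forward_sequence(x, p)
        s1 = lstm_cell_forward(x[0], LSTMState.zeros(6), p)
        assert np.allclose(y[0], s1.h @ p.Wout + p.bout, atol=1e-12)


class TestGateRanges:
    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000), T=st.integers(1, 20))
    def test_hidden_state_bounded_and_gates_open(self, seed, T):
        rng = np.random.default_rng(seed)
        p = random_params(rng, 2, 4)
        state = LSTMState.zeros(4)
        for t in range(T):
            state = lstm_cell_forward(5 * rng.standard_normal(2), state, p)
            assert np.all(np.abs(state.h) <= 1.0)


class TestDropoutAndDeterminism:
    def test_eval_mode_deterministic(self):
        rng = np.random.default_rng(0)
        p = random_params(rng, 4, 8)
        X = rng.standard_normal((20, 4))
        assert np.array_equal(forward_sequence(X, p), forward_sequence(X, p))

    def test_zero_dropout_training_equals_eval(self):
        rng = np.random.default_rng(1)
        p = random_params(rng, 4, 8)
        X = rng.standard_normal((20, 4))
        y_train = forward_sequence(X, p, training=True, dropout_p=0.0,
                                   rng=np.random.default_rng(5))
        assert np.allclose(y_train, forward_sequence(X, p))

    def test_dropout_changes_training_output_only(self):
        rng = np.random.default_rng(1)
        p = random_params(rng, 4, 8)
        X = rng.standard_normal((20, 4))
        y = forward_sequence(X, p, training=True, dropout_p=0.5,
                             rng=np.random.default_rng(5))
        assert not np.allclose(y, forward_sequence(X, p))


class TestGradients:
    @pytest.mark.parametrize("g_gate", ["sigmoid_as_printed", "tanh_standard"])
    def test_backprop_matches_finite_differences(self, g_gate):
        rng = np.random.default_rng(7)
        p = random_params(rng, 2, 3, g_gate)
        X = rng.standard_normal((1, 4, 2))
        Y = rng.standard_normal((1, 4, 6))
        assert finite_difference_check(p, X, Y, n_probes=40, seed=1) < 1e-4

    def test_one_weight_against_direct_numeric_derivative(self):
        """Fully independent probe: perturb one weight, re-run the forward."""
        rng = np.random.default_rng(8)
        p = random_params(rng, 2, 3)
        X = rng.standard_normal((1, 5, 2))
        Y = rng.standard_normal((1, 5, 6))
        _, grads = loss_and_grads(p, X, Y, training=False)
        eps = 1e-6
        p.Wout[1, 2] += eps
        lp = float(np.mean((forward_sequence(X[0], p) - Y[0]) ** 2))
        p.Wout[1, 2] -= 2 * eps
        lm = float(np.mean((forward_sequence(X[0], p) - Y[0]) ** 2))
        p.Wout[1, 2] += eps
        num = (lp - lm) / (2 * eps)
        assert abs(num - grads["Wout"][1, 2]) < 1e-6 * max(1.0, abs(num))


def _linear_map_dataset(seed=0, n=2400, d=5, window=16):
    """Noise-free target = fixed linear map of smooth inputs: identifiable."""
    rng = np.random.default_rng(seed)
    from scipy.signal import butter, sosfiltfilt
    sos = butter(2, 0.05, output="sos")
    X = sosfiltfilt(sos, rng.standard_normal((n, d)), axis=0)
    X = (X - X.mean(0)) / X.std(0)
    W = rng.uniform(-1, 1, size=(d, 6))
    Y = X @ W + rng.uniform(-1, 1, size=6)
    half = n // 2
    return SequenceDataset(
        pattern=get_pattern(5),  # any pattern tag; dim comes from arrays
        X_train=X[:half], Y_train=Y[:half], X_test=X[half:], Y_test=Y[half:],
        t_train=np.arange(half) / 74.074, t_test=np.arange(half, n) / 74.074,
        input_stats=ChannelStats(np.zeros(d), np.ones(d), [f"c{i}" for i in range(d)]),
        window_length=window)


class TestTraining:
    def test_learns_linear_map_within_50_epochs(self):
        ds = _linear_map_dataset()
        cfg = TrainConfig(seed=0, hidden_size=32, dropout_p=0.0,
                          max_epochs=50, batch_size=2)
        model = train_model(ds, cfg)
        est = predict_wrench(model, ds.X_test)
        worst = max(percent_rmse(est[:, j], ds.Y_test[:, j]) for j in range(6))
        assert worst < 5.0

    def test_seeded_training_is_reproducible(self):
        ds = _linear_map_dataset(n=600)
        cfg = TrainConfig(seed=3, hidden_size=8, max_epochs=5, batch_size=4)
        m1 = train_model(ds, cfg)
        m2 = train_model(ds, cfg)
        assert m1.log[-1]["train_loss"] == m2.log[-1]["train_loss"]
        assert np.array_equal(m1.params.Wout, m2.params.Wout)

    def test_training_loss_trends_down(self):
        ds = _linear_map_dataset(n=1200)
        cfg = TrainConfig(seed=1, hidden_size=16, dropout_p=0.0,
                          max_epochs=30, batch_size=8)
        model = train_model(ds, cfg)
        losses = [row["train_loss"] for row in model.log]
        # monotone trend up to 5% tolerance
        for a, b in zip(losses, losses[1:]):
            assert b <= 1.05 * a
        assert losses[-1] < losses[0]

    def test_prediction_contract(self):
        ds = _linear_map_dataset(n=400)
        model = train_model(ds, TrainConfig(seed=0, hidden_size=8,
                                            max_epochs=2, batch_size=4))
        est1 = predict_wrench(model, ds.X_test)
        est2 = predict_wrench(model, ds.X_test)
        assert est1.shape == (len(ds.X_test), 6)
        assert np.array_equal(est1, est2)
        with pytest.raises(ModelError):
            predict_wrench(model, ds.X_test[:, :3])

    def test_mean_baseline_shape(self):
        ds = _linear_map_dataset(n=200)
        base = mean_predictor_baseline(ds.Y_train, ds.Y_test)
        assert base.shape == ds.Y_test.shape
        assert np.allclose(base[0], ds.Y_train.mean(0))
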