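"""From-scratch LSTM regressor for 6-channel wrench estimation.

The recurrent cell follows the four-gate formulation with a forget gate f,
generation gate g, input gate i and output gate o:

    f_t = sigma(x_t Wxf + h_{t-1} Whf + bf)
    g_t = phi  (x_t Wxg + h_{t-1} Whg + bg)
    i_t = sigma(x_t Wxi + h_{t-1} Whi + bi)
    o_t = sigma(x_t Wxo + h_{t-1} Who + bo)
    c_t = f_t * c_{t-1} + g_t * i_t
    h_t = o_t * tanh(c_t)

where sigma is the logistic sigmoid and phi is configurable: the default
``sigmoid_as_printed`` uses the sigmoid for the generation gate as well (the
formulation this package reproduces), while ``tanh_standard`` selects the
conventional tanh generation gate. The sigmoid form constrains g*i to be
positive, so the cell state drifts toward positive values; both variants are
supported and tested.

A per-frame affine head maps the (dropout-regularized) hidden state to the
six wrench channels; training minimizes MSE with Adam over truncated
non-overlapping windows, carrying no state across window boundaries.
Gradients are computed analytically by backpropagation through time and are
validated against finite differences.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .errors import ModelError, TrainingDivergedError
from .dataset import SequenceDataset, make_windows

N_OUTPUTS = 6
GATE_ORDER = ("f", "g", "i", "o")


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LSTMParams:
    """All weights of the cell plus the affine output head.

    Input-to-gate matrices are (d, H), hidden-to-gate (H, H), biases (H,);
    the head maps H -> 6. ``g_gate`` selects the generation-gate
    nonlinearity: 'sigmoid_as_printed' (default) or 'tanh_standard'.
    """

    Wxf: np.ndarray
    Wxg: np.ndarray
    Wxi: np.ndarray
    Wxo: np.ndarray
    Whf: np.ndarray
    Whg: np.ndarray
    Whi: np.ndarray
    Who: np.ndarray
    bf: np.ndarray
    bg: np.ndarray
    bi: np.ndarray
    bo: np.ndarray
    Wout: np.ndarray
    bout: np.ndarray
    g_gate: str = "sigmoid_as_printed"

    @property
    def d(self) -> int:
        return self.Wxf.shape[0]

    @property
    def H(self) -> int:
        return self.Wxf.shape[1]

    def g_nonlin(self, z: np.ndarray) -> np.ndarray:
        return sigmoid(z) if self.g_gate == "sigmoid_as_printed" else np.tanh(z)

    # --- stacked views used by the vectorized training path ---------------

    def stacked(self):
        Wx = np.concatenate([self.Wxf, self.Wxg, self.Wxi, self.Wxo], axis=1)
        Wh = np.concatenate([self.Whf, self.Whg, self.Whi, self.Who], axis=1)
        b = np.concatenate([self.bf, self.bg, self.bi, self.bo])
        return Wx, Wh, b

    def set_stacked(self, Wx, Wh, b) -> None:
        H = self.H
        (self.Wxf, self.Wxg, self.Wxi, self.Wxo) = np.split(Wx, 4, axis=1)
        (self.Whf, self.Whg, self.Whi, self.Who) = np.split(Wh, 4, axis=1)
        (self.bf, self.bg, self.bi, self.bo) = np.split(b, 4)

    def copy(self) -> "LSTMParams":
        return copy.deepcopy(self)


@dataclass
class LSTMState:
    """Hidden and cell state at one time index."""

    h: np.ndarray
    c: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, H: int, batch: int | None = None) -> "LSTMState":
        shape = (H,) if batch is None else (batch, H)
        return cls(h=np.zeros(shape), c=np.zeros(shape), t=0)


def init_params(d: int, H: int = 64, seed: int = 0,
                g_gate: str = "sigmoid_as_printed") -> LSTMParams:
    """Seeded uniform(+-1/sqrt(H)) init; forget-gate bias +1 for long memory."""
    rng = np.random.default_rng(seed)
    s = 1.0 / np.sqrt(H)

    def u(*shape):
        return rng.uniform(-s, s, size=shape)

    return LSTMParams(
        Wxf=u(d, H), Wxg=u(d, H), Wxi=u(d, H), Wxo=u(d, H),
        Whf=u(H, H), Whg=u(H, H), Whi=u(H, H), Who=u(H, H),
        bf=np.ones(H), bg=np.zeros(H), bi=np.zeros(H), bo=np.zeros(H),
        Wout=u(H, N_OUTPUTS), bout=np.zeros(N_OUTPUTS),
        g_gate=g_gate,
    )


def lstm_cell_forward(x_t: np.ndarray, state: LSTMState,
                      params: LSTMParams) -> LSTMState:
    """One recurrence step, gate by gate, exactly as formulated above."""
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape[-1] != params.d:
        raise ModelError(
            f"input dimension {x_t.shape[-1]} != parameter dimension {params.d}")
    h, c = state.h, state.c
    f = sigmoid(x_t @ params.Wxf + h @ params.Whf + params.bf)
    g = params.g_nonlin(x_t @ params.Wxg + h @ params.Whg + params.bg)
    i = sigmoid(x_t @ params.Wxi + h @ params.Whi + params.bi)
    o = sigmoid(x_t @ params.Wxo + h @ params.Who + params.bo)
    c_new = f * c + g * i
    h_new = o * np.tanh(c_new)
    return LSTMState(h=h_new, c=c_new, t=state.t + 1)


# ---------------------------------------------------------------------------
# vectorized forward/backward over (batch, time) windows
# ---------------------------------------------------------------------------

class _Cache:
    __slots__ = ("X", "F", "Gg", "I", "O", "C", "TC", "Hs", "h0", "c0",
                 "mask", "Hd")


def _forward(X: np.ndarray, params: LSTMParams, training: bool = False,
             dropout_p: float = 0.0, rng: np.random.Generator | None = None,
             initial_state: LSTMState | None = None,
             want_cache: bool = False):
    """Run the cell over X (B, T, d), apply dropout + head per frame."""
    B, T, d = X.shape
    H = params.H
    Wx, Wh, b = params.stacked()
    if initial_state is None:
        h = np.zeros((B, H))
        c = np.zeros((B, H))
    else:
        h, c = np.broadcast_to(initial_state.h, (B, H)).copy(), \
            np.broadcast_to(initial_state.c, (B, H)).copy()
    XW = X.reshape(B * T, d) @ Wx
    XW = XW.reshape(B, T, 4 * H) + b

    cache = _Cache() if want_cache else None
    if want_cache:
        cache.X = X
        cache.h0, cache.c0 = h.copy(), c.copy()
        cache.F = np.empty((B, T, H)); cache.Gg = np.empty((B, T, H))
        cache.I = np.empty((B, T, H)); cache.O = np.empty((B, T, H))
        cache.C = np.empty((B, T, H)); cache.TC = np.empty((B, T, H))
        cache.Hs = np.empty((B, T, H))

    use_sigmoid_g = params.g_gate == "sigmoid_as_printed"
    Hseq = np.empty((B, T, H))
    for t in range(T):
        z = XW[:, t] + h @ Wh
        f = sigmoid(z[:, :H])
        g = sigmoid(z[:, H:2 * H]) if use_sigmoid_g else np.tanh(z[:, H:2 * H])
        i = sigmoid(z[:, 2 * H:3 * H])
        o = sigmoid(z[:, 3 * H:])
        c = f * c + g * i
        tc = np.tanh(c)
        h = o * tc
        Hseq[:, t] = h
        if want_cache:
            cache.F[:, t], cache.Gg[:, t] = f, g
            cache.I[:, t], cache.O[:, t] = i, o
            cache.C[:, t], cache.TC[:, t] = c, tc

    if training and dropout_p > 0:
        if rng is None:
            rng = np.random.default_rng()
        mask = (rng.random(Hseq.shape) >= dropout_p) / (1.0 - dropout_p)
    else:
        mask = None
    Hd = Hseq if mask is None else Hseq * mask
    Y = Hd @ params.Wout + params.bout
    if want_cache:
        cache.Hs = Hseq
        cache.mask = mask
        cache.Hd = Hd
        return Y, cache
    return Y


def forward_sequence(X: np.ndarray, params: LSTMParams,
                     initial_state: LSTMState | None = None,
                     training: bool = False, dropout_p: float = 0.0,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """6-channel output for a (T, d) window or (B, T, d) batch of windows.

    Evaluation mode (the default) is deterministic; dropout on the hidden
    state is applied only when ``training`` is True and ``dropout_p`` > 0.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    if X.shape[-1] != params.d:
        raise ModelError(
            f"input dimension {X.shape[-1]} != parameter dimension {params.d}")
    Y = _forward(X, params, training=training, dropout_p=dropout_p, rng=rng,
                 initial_state=initial_state)
    return Y[0] if single else Y


def _backward(dY: np.ndarray, params: LSTMParams, cache: _Cache) -> dict:
    """BPTT gradients of a scalar loss with upstream dY (B, T, 6)."""
    B, T, H = cache.Hs.shape
    Wx, Wh, _ = params.stacked()
    use_sigmoid_g = params.g_gate == "sigmoid_as_printed"

    dWout = cache.Hd.reshape(B * T, H).T @ dY.reshape(B * T, N_OUTPUTS)
    dbout = dY.sum(axis=(0, 1))
    dHd = dY @ params.Wout.T
    if cache.mask is not None:
        dHd = dHd * cache.mask

    dZ = np.empty((B, T, 4 * H))
    dh_carry = np.zeros((B, H))
    dc_carry = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        f, g = cache.F[:, t], cache.Gg[:, t]
        i, o = cache.I[:, t], cache.O[:, t]
        tc = cache.TC[:, t]
        c_prev = cache.C[:, t - 1] if t > 0 else cache.c0
        dh = dHd[:, t] + dh_carry
        dc = dc_carry + dh * o * (1.0 - tc * tc)
        do = dh * tc
        df = dc * c_prev
        dg = dc * i
        di = dc * g
        dz = dZ[:, t]
        dz[:, :H] = df * f * (1.0 - f)
        dz[:, H:2 * H] = dg * (g * (1.0 - g) if use_sigmoid_g else 1.0 - g * g)
        dz[:, 2 * H:3 * H] = di * i * (1.0 - i)
        dz[:, 3 * H:] = do * o * (1.0 - o)
        dh_carry = dz @ Wh.T
        dc_carry = dc * f

    Hprev = np.concatenate([cache.h0[:, None], cache.Hs[:, :-1]], axis=1)
    d_in = cache.X.shape[-1]
    dWx = cache.X.reshape(B * T, d_in).T @ dZ.reshape(B * T, 4 * H)
    dWh = Hprev.reshape(B * T, H).T @ dZ.reshape(B * T, 4 * H)
    db = dZ.sum(axis=(0, 1))
    return {"Wx": dWx, "Wh": dWh, "b": db, "Wout": dWout, "bout": dbout}


def loss_and_grads(params: LSTMParams, X: np.ndarray, Y: np.ndarray,
                   training: bool = True, dropout_p: float = 0.0,
                   rng: np.random.Generator | None = None):
    """Mean-squared error over all frames and channels, plus its gradients."""
    Yhat, cache = _forward(X, params, training=training, dropout_p=dropout_p,
                           rng=rng, want_cache=True)
    err = Yhat - Y
    loss = float(np.mean(err ** 2))
    dY = 2.0 * err / err.size
    grads = _backward(dY, params, cache)
    return loss, grads


def finite_difference_check(params: LSTMParams, X: np.ndarray, Y: np.ndarray,
                            n_probes: int = 30, eps: float = 1e-6,
                            seed: int = 0) -> float:
    """Max relative |analytic - numerical| gradient error over random probes.

    Central differences on a sample of scalar parameters; dropout off so the
    loss is deterministic. Used as the gradient-correctness diagnostic.
    """
    rng = np.random.default_rng(seed)
    _, grads = loss_and_grads(params, X, Y, training=False, dropout_p=0.0)
    Wx, Wh, b = params.stacked()
    arrays = {"Wx": Wx, "Wh": Wh, "b": b,
              "Wout": params.Wout, "bout": params.bout}

    def set_param(name, idx, val):
        arrays[name].flat[idx] = val
        if name in ("Wx", "Wh", "b"):
            params.set_stacked(arrays["Wx"], arrays["Wh"], arrays["b"])

    worst = 0.0
    names = list(arrays)
    for _ in range(n_probes):
        name = names[int(rng.integers(len(names)))]
        idx = int(rng.integers(arrays[name].size))
        orig = arrays[name].flat[idx]
        set_param(name, idx, orig + eps)
        lp, _ = loss_and_grads(params, X, Y, training=False)
        set_param(name, idx, orig - eps)
        lm, _ = loss_and_grads(params, X, Y, training=False)
        set_param(name, idx, orig)
        num = (lp - lm) / (2 * eps)
        ana = grads[name].flat[idx]
        denom = max(abs(num), abs(ana), 1e-8)
        worst = max(worst, abs(num - ana) / denom)
    return worst


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (batch 64, lr 1e-3, Adam, 50% dropout)."""

    batch_size: int = 64
    learning_rate: float = 1e-3
    dropout_p: float = 0.5
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.2   # held-out tail of the training half
    seed: int = 0
    hidden_size: int = 64
    g_gate: str = "sigmoid_as_printed"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")


class _Adam:
    def __init__(self, shapes: dict, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, values: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            values[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


@dataclass
class TrainedModel:
    """Fitted LSTM + the scalers needed to emit physical-unit wrench."""

    params: LSTMParams
    target_mean: np.ndarray
    target_scale: np.ndarray
    pattern_id: int
    train_config: TrainConfig
    log: list = field(default_factory=list)


def _batched(windows_x, windows_y, batch_size, rng):
    """Yield same-length stacked batches (full windows shuffled, partial last)."""
    full = [(x, y) for x, y in zip(windows_x, windows_y)
            if len(x) == len(windows_x[0])]
    partial = [(x, y) for x, y in zip(windows_x, windows_y)
               if len(x) != len(windows_x[0])]
    order = rng.permutation(len(full))
    for s in range(0, len(full), batch_size):
        idx = order[s:s + batch_size]
        yield (np.stack([full[j][0] for j in idx]),
               np.stack([full[j][1] for j in idx]))
    for x, y in partial:
        yield x[None], y[None]


def train_model(dataset: SequenceDataset, config: TrainConfig | None = None):
    """Fit the LSTM on the training half with Adam and early stopping.

    The last ``val_fraction`` of the training half is held out for early
    stopping (patience on validation MSE); windows never straddle the
    fit/validation boundary. Targets are z-scored internally with training
    statistics and predictions are mapped back to physical units, so the six
    channels carry equal weight in the loss regardless of their native
    scales. Deterministic given ``config.seed``.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)

    X, Y = dataset.X_train, dataset.Y_train
    n_fit = int(len(X) * (1.0 - config.val_fraction))
    ymean = Y[:n_fit].mean(axis=0)
    yscale = Y[:n_fit].std(axis=0, ddof=0)
    yscale = np.where(yscale == 0, 1.0, yscale)
    Ys = (Y - ymean) / yscale

    wx = make_windows(X[:n_fit], dataset.window_length)
    wy = make_windows(Ys[:n_fit], dataset.window_length)
    Xval, Yval = X[n_fit:], Ys[n_fit:]

    params = init_params(dataset.dim, H=config.hidden_size,
                         seed=config.seed, g_gate=config.g_gate)
    Wx0, Wh0, b0 = params.stacked()
    values = {"Wx": Wx0, "Wh": Wh0, "b": b0,
              "Wout": params.Wout, "bout": params.bout}
    adam = _Adam({k: v.shape for k, v in values.items()}, config.learning_rate)

    def sync():
        params.set_stacked(values["Wx"], values["Wh"], values["b"])
        params.Wout, params.bout = values["Wout"], values["bout"]

    best_val = np.inf
    best_params = None
    bad_epochs = 0
    log = []
    for epoch in range(config.max_epochs):
        losses = []
        for xb, yb in _batched(wx, wy, config.batch_size, rng):
            sync()
            loss, grads = loss_and_grads(params, xb, yb, training=True,
                                         dropout_p=config.dropout_p, rng=rng)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}")
            adam.step(values, grads)
            losses.append(loss)
        sync()
        if len(Xval):
            yv = forward_sequence(Xval, params)
            val_loss = float(np.mean((yv - Yval) ** 2))
        else:
            val_loss = float(np.mean(losses))
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "val_loss": val_loss})
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = params.copy()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break
    if best_params is not None:
        params = best_params
    return TrainedModel(params=params, target_mean=ymean, target_scale=yscale,
                        pattern_id=dataset.pattern.id, train_config=config,
                        log=log)


def predict_wrench(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Deterministic 6-channel wrench estimate (physical units) for (T, d) X."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.params.d:
        raise ModelError(
            f"feature dimension {X.shape[-1]} does not match the trained "
            f"pattern (expected {model.params.d})")
    Ys = forward_sequence(X, model.params)
    return Ys * model.target_scale + model.target_mean


def mean_predictor_baseline(Y_train: np.ndarray, Y_test: np.ndarray) -> np.ndarray:
    """Constant train-mean prediction over the test half, for RMSE baselines."""
    return np.tile(Y_train.mean(axis=0), (len(Y_test), 1))
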