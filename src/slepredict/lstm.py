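"""LSTM sequence classifier implemented from its defining gate equations.

A single-layer LSTM with input, forget and output gates,

    i_t = sigma(W_i [h_{t-1}, x_t] + b_i)
    f_t = sigma(W_f [h_{t-1}, x_t] + b_f)
    o_t = sigma(W_o [h_{t-1}, x_t] + b_o)
    C~_t = tanh(W_c [h_{t-1}, x_t] + b_c)
    C_t = f_t * C_{t-1} + i_t * C~_t
    h_t = o_t * tanh(C_t)

(`*` elementwise), sharing one set of weights across all time steps.  The
class-1 probability is the logistic of an affine map of the last hidden
state.  Training minimizes binary cross-entropy with mini-batch Adam;
gradients are computed by backpropagation through time (exact, verified
against finite differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .features import PanelScaler
from .imbalance import oversample

GATES = ("i", "f", "o", "c")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class LSTMParams:
    """Gate weight matrices over [h_{t-1}, x_t], biases, and the output map.

    Each gate matrix has shape ``hidden_size x (hidden_size + input_dim)``;
    its first ``hidden_size`` columns act on the previous hidden state and
    the remainder on the current input.
    """

    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray
    w_out: np.ndarray
    b_out: float

    def __post_init__(self) -> None:
        H = self.b_i.shape[0]
        D = self.W_i.shape[1] - H
        for name in ("W_i", "W_f", "W_o", "W_c"):
            if getattr(self, name).shape != (H, H + D):
                raise ValueError(f"{name} must have shape ({H}, {H + D})")
        for name in ("b_f", "b_o", "b_c"):
            if getattr(self, name).shape != (H,):
                raise ValueError(f"{name} must have shape ({H},)")
        if self.w_out.shape != (H,):
            raise ValueError(f"w_out must have shape ({H},)")

    @property
    def hidden_size(self) -> int:
        return self.b_i.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_i.shape[1] - self.hidden_size


def save_params(params: LSTMParams, path) -> None:
    """Checkpoint the full parameter set; reload reproduces outputs exactly."""
    np.savez(
        path,
        **{f"W_{g}": getattr(params, f"W_{g}") for g in GATES},
        **{f"b_{g}": getattr(params, f"b_{g}") for g in GATES},
        w_out=params.w_out,
        b_out=np.array(params.b_out),
    )


def load_params(path) -> LSTMParams:
    with np.load(path) as d:
        return LSTMParams(
            **{f"W_{g}": d[f"W_{g}"] for g in GATES},
            **{f"b_{g}": d[f"b_{g}"] for g in GATES},
            w_out=d["w_out"],
            b_out=float(d["b_out"]),
        )


def init_params(input_dim: int, hidden_size: int, rng: np.random.Generator) -> LSTMParams:
    """Uniform(-s, s) initialization with s = 1/sqrt(hidden + input)."""
    s = 1.0 / np.sqrt(hidden_size + input_dim)
    shape = (hidden_size, hidden_size + input_dim)
    return LSTMParams(
        W_i=rng.uniform(-s, s, shape),
        W_f=rng.uniform(-s, s, shape),
        W_o=rng.uniform(-s, s, shape),
        W_c=rng.uniform(-s, s, shape),
        b_i=np.zeros(hidden_size),
        b_f=np.ones(hidden_size),  # standard forget-gate bias init
        b_o=np.zeros(hidden_size),
        b_c=np.zeros(hidden_size),
        w_out=rng.uniform(-s, s, hidden_size),
        b_out=0.0,
    )


def lstm_cell(
    params: LSTMParams, x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the gate equations; accepts vectors or (batch, dim) arrays."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    if x_t.shape[-1] != params.input_dim or h_prev.shape[-1] != params.hidden_size:
        raise ValueError(
            f"expected input_dim={params.input_dim}, hidden={params.hidden_size}; "
            f"got x_t {x_t.shape}, h_prev {h_prev.shape}"
        )
    u = np.concatenate([h_prev, x_t], axis=-1)
    i = _sigmoid(u @ params.W_i.T + params.b_i)
    f = _sigmoid(u @ params.W_f.T + params.b_f)
    o = _sigmoid(u @ params.W_o.T + params.b_o)
    c_tilde = np.tanh(u @ params.W_c.T + params.b_c)
    c = f * c_prev + i * c_tilde
    h = o * np.tanh(c)
    return h, c


def lstm_forward(params: LSTMParams, sequence: np.ndarray) -> np.ndarray | float:
    """Class-1 probability after running the cell over all k steps.

    ``sequence`` may be one sequence (k, d) or a batch (n, k, d); the
    initial hidden and cell states are zero.
    """
    seq = np.asarray(sequence, dtype=float)
    single = seq.ndim == 2
    if single:
        seq = seq[None]
    if seq.shape[1] == 0:
        raise ValueError("sequence must have at least one time step")
    n = seq.shape[0]
    h = np.zeros((n, params.hidden_size))
    c = np.zeros((n, params.hidden_size))
    for t in range(seq.shape[1]):
        h, c = lstm_cell(params, seq[:, t, :], h, c)
    logit = h @ params.w_out + params.b_out
    p = _sigmoid(logit)
    return float(p[0]) if single else p


@dataclass
class TrainConfig:
    """Optimizer settings: 50 epochs, batch 72, Adam at 1e-4 by default."""

    epochs: int = 50
    batch_size: int = 72
    learning_rate: float = 0.0001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


def _params_to_dict(p: LSTMParams) -> dict[str, np.ndarray]:
    return {
        **{f"W_{g}": getattr(p, f"W_{g}").copy() for g in GATES},
        **{f"b_{g}": getattr(p, f"b_{g}").copy() for g in GATES},
        "w_out": p.w_out.copy(),
        "b_out": np.array(float(p.b_out)),
    }


def _dict_to_params(d: dict[str, np.ndarray]) -> LSTMParams:
    return LSTMParams(
        **{f"W_{g}": d[f"W_{g}"] for g in GATES},
        **{f"b_{g}": d[f"b_{g}"] for g in GATES},
        w_out=d["w_out"],
        b_out=float(d["b_out"]),
    )


def loss_and_gradients(
    theta: dict[str, np.ndarray], X: np.ndarray, y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean binary cross-entropy and its exact gradients (BPTT)."""
    n, k, d = X.shape
    H = theta["b_i"].shape[0]
    h = np.zeros((n, H))
    c = np.zeros((n, H))
    cache = []
    for t in range(k):
        u = np.concatenate([h, X[:, t, :]], axis=1)
        i = _sigmoid(u @ theta["W_i"].T + theta["b_i"])
        f = _sigmoid(u @ theta["W_f"].T + theta["b_f"])
        o = _sigmoid(u @ theta["W_o"].T + theta["b_o"])
        g = np.tanh(u @ theta["W_c"].T + theta["b_c"])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        cache.append((u, i, f, o, g, c, c_new))
        h, c = h_new, c_new

    logit = h @ theta["w_out"] + float(theta["b_out"])
    # numerically stable BCE: softplus(logit) - y*logit
    loss = float(np.mean(np.logaddexp(0.0, logit) - y * logit))

    grads = {key: np.zeros_like(val) for key, val in theta.items()}
    dlogit = (_sigmoid(logit) - y) / n
    grads["w_out"] = h.T @ dlogit
    grads["b_out"] = np.array(dlogit.sum())
    dh = np.outer(dlogit, theta["w_out"])
    dc = np.zeros((n, H))
    for t in range(k - 1, -1, -1):
        u, i, f, o, g, c_prev, c_t = cache[t]
        tc = np.tanh(c_t)
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc**2)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dz = {
            "i": di * i * (1.0 - i),
            "f": df * f * (1.0 - f),
            "o": do * o * (1.0 - o),
            "c": dg * (1.0 - g**2),
        }
        dh = np.zeros((n, H))
        for gate in GATES:
            grads[f"W_{gate}"] += dz[gate].T @ u
            grads[f"b_{gate}"] += dz[gate].sum(axis=0)
            dh += dz[gate] @ theta[f"W_{gate}"][:, :H]
        dc = dc * f
    return loss, grads


def train_lstm(
    X: np.ndarray,
    y: np.ndarray,
    hidden_size: int = 32,
    config: TrainConfig | None = None,
    init: LSTMParams | None = None,
) -> tuple[LSTMParams, list[float]]:
    """Mini-batch Adam training; returns fitted params and per-epoch losses."""
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k, d = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    rng = np.random.default_rng(config.seed)
    theta = _params_to_dict(init if init is not None else init_params(d, hidden_size, rng))

    m = {key: np.zeros_like(v) for key, v in theta.items()}
    v = {key: np.zeros_like(val) for key, val in theta.items()}
    step = 0
    losses = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = loss_and_gradients(theta, X[idx], y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {_epoch}, batch {n_batches}"
                )
            epoch_loss += loss
            n_batches += 1
            step += 1
            for key in theta:
                m[key] = config.beta1 * m[key] + (1 - config.beta1) * grads[key]
                v[key] = config.beta2 * v[key] + (1 - config.beta2) * grads[key] ** 2
                m_hat = m[key] / (1 - config.beta1**step)
                v_hat = v[key] / (1 - config.beta2**step)
                theta[key] = theta[key] - config.learning_rate * m_hat / (
                    np.sqrt(v_hat) + config.eps
                )
        losses.append(epoch_loss / max(1, n_batches))
    return _dict_to_params(theta), losses


class LSTMClassifier(ClassifierMixin, BaseEstimator):
    """Sequence classifier over (n, k, d) tensors with minority oversampling.

    ``fit`` duplicates each minority sequence r-1 times (r = rounded
    majority/minority ratio), standardizes continuous step-features on the
    training data, and trains the NumPy LSTM with mini-batch Adam.  The
    default training settings (50 epochs, batch 72, learning rate 1e-4)
    suit cohort-scale data; smaller toy problems typically want a larger
    learning rate.
    """

    def __init__(
        self,
        hidden_size: int = 32,
        epochs: int = 50,
        batch_size: int = 72,
        learning_rate: float = 0.0001,
        oversample: bool = True,
        scale: bool = True,
        binary_mask: np.ndarray | None = None,
        random_state: int | None = None,
    ):
        self.hidden_size = hidden_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.oversample = oversample
        self.scale = scale
        self.binary_mask = binary_mask
        self.random_state = random_state

    def _check_X(self, X) -> np.ndarray:
        X = check_array(X, allow_nd=True, dtype=float)
        if X.ndim != 3:
            raise ValueError(f"X must be a 3-D (n, k, d) tensor, got ndim={X.ndim}")
        return X

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("LSTMClassifier requires binary labels")
        y01 = (y == self.classes_[1]).astype(float)

        if self.oversample:
            self.oversample_indices_ = oversample(y01.astype(int))
        else:
            self.oversample_indices_ = np.arange(X.shape[0])

        if self.scale:
            self.scaler_ = PanelScaler(binary_mask=self.binary_mask).fit(X)
            X_t = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            X_t = X

        seed = int(np.random.default_rng(self.random_state).integers(2**31))
        cfg = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=seed,
        )
        self.params_, self.losses_ = train_lstm(
            X_t[self.oversample_indices_],
            y01[self.oversample_indices_],
            hidden_size=self.hidden_size,
            config=cfg,
        )
        self.n_features_in_ = X.shape[2]
        return self

    def decision_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = self._check_X(X)
        X_t = self.scaler_.transform(X) if self.scaler_ is not None else X
        return lstm_forward(self.params_, X_t)

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_scores(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        s = self.decision_scores(X)
        return self.classes_[(s >= 0.5).astype(int)]
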