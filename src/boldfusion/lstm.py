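"""Two-layer LSTM branch: gate equations, sequence encoder, and training.

The recurrent cell follows the standard gate formulation: with the gate
input ``z_t = [h_{t-1}, x_t]``,

    i_t = sigmoid(W_i z_t + b_i)        (input gate)
    f_t = sigmoid(W_f z_t + b_f)        (forget gate)
    o_t = sigmoid(W_o z_t + b_o)        (output gate)
    g_t = tanh(W_c z_t + b_c)           (candidate cell)
    c_t = i_t * g_t + f_t * c_{t-1}
    h_t = o_t * tanh(c_t)

The branch feature ``fL`` is the last-time-step hidden state of the top
layer (100 units under the Stage I preset, giving fL in R^100). Training
attaches a temporary softmax head on the task labels, runs full
backpropagation through time with Adam, and discards the head; inter-layer
dropout (inverted) is active during training only, so inference is
deterministic.

Everything here is plain numpy; weights live in :class:`LstmParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LstmLayerParams",
    "LstmParams",
    "LstmState",
    "init_lstm_params",
    "lstm_cell_step",
    "lstm_encode",
    "train_lstm_branch",
    "LstmFeaturizer",
    "STAGE1_PRESET",
    "STAGE2_PRESET",
]

#: Stage I preset: two layers, top layer forced to 100 units by fL in R^100.
STAGE1_PRESET = {"hidden_sizes": (150, 100), "dropout": (0.0, 0.0)}
#: Stage II preset: 150 and 100 hidden units with dropout ratios 0.2 and 0.1.
STAGE2_PRESET = {"hidden_sizes": (150, 100), "dropout": (0.2, 0.1)}

_GATES = 4  # i, f, g (candidate), o — stacked row blocks of W


@dataclass
class LstmLayerParams:
    """One layer's fused gate weights: ``W`` is (4H, H+D), ``b`` is (4H,).

    Row blocks are ordered input gate, forget gate, candidate, output gate;
    columns act on the concatenation ``[h_{t-1}, x_t]``.
    """

    W: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W)
        self.b = np.asarray(self.b)
        if self.W.ndim != 2 or self.W.shape[0] % _GATES:
            raise ValueError("W must be (4H, H+D)")
        h = self.W.shape[0] // _GATES
        if self.W.shape[1] < h or self.b.shape != (self.W.shape[0],):
            raise ValueError("inconsistent LSTM layer shapes")

    @property
    def hidden_size(self) -> int:
        return self.W.shape[0] // _GATES

    @property
    def input_size(self) -> int:
        return self.W.shape[1] - self.hidden_size

    # Per-gate views of the fused parameter block.
    @property
    def W_i(self):
        return self.W[: self.hidden_size]

    @property
    def W_f(self):
        return self.W[self.hidden_size : 2 * self.hidden_size]

    @property
    def W_c(self):
        return self.W[2 * self.hidden_size : 3 * self.hidden_size]

    @property
    def W_o(self):
        return self.W[3 * self.hidden_size :]

    @property
    def b_i(self):
        return self.b[: self.hidden_size]

    @property
    def b_f(self):
        return self.b[self.hidden_size : 2 * self.hidden_size]

    @property
    def b_c(self):
        return self.b[2 * self.hidden_size : 3 * self.hidden_size]

    @property
    def b_o(self):
        return self.b[3 * self.hidden_size :]


@dataclass
class LstmParams:
    """A stacked (multi-layer) LSTM plus per-layer dropout rates."""

    layers: list[LstmLayerParams]
    dropout: tuple[float, ...] = ()
    loss_history_: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("need at least one layer")
        if not self.dropout:
            self.dropout = (0.0,) * len(self.layers)
        if len(self.dropout) != len(self.layers):
            raise ValueError("one dropout rate per layer required")
        if any(not 0 <= d < 1 for d in self.dropout):
            raise ValueError("dropout rates must lie in [0, 1)")
        for lo, hi in zip(self.layers, self.layers[1:]):
            if hi.input_size != lo.hidden_size:
                raise ValueError("stacked layer sizes are inconsistent")

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return tuple(l.hidden_size for l in self.layers)

    @property
    def feature_size(self) -> int:
        return self.layers[-1].hidden_size


@dataclass
class LstmState:
    """Hidden and cell state of one layer (matching trailing dimension)."""

    h: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h)
        self.c = np.asarray(self.c)
        if self.h.shape != self.c.shape:
            raise ValueError("h and c must have matching shapes")


def init_lstm_params(
    input_size: int,
    hidden_sizes: tuple[int, ...],
    dropout: tuple[float, ...] | None = None,
    seed: int = 0,
    scale: float | None = None,
) -> LstmParams:
    """Glorot-uniform initialised stacked LSTM parameters (seeded)."""
    rng = np.random.default_rng(seed)
    layers = []
    d = input_size
    for h in hidden_sizes:
        lim = scale if scale is not None else np.sqrt(6.0 / (h + d + h))
        W = rng.uniform(-lim, lim, size=(_GATES * h, h + d))
        b = np.zeros(_GATES * h)
        b[h : 2 * h] = 1.0  # forget-gate bias 1: remember by default
        layers.append(LstmLayerParams(W, b))
        d = h
    return LstmParams(layers, tuple(dropout) if dropout else ())


def _sigmoid(x):
    from scipy.special import expit

    return expit(x)


def lstm_cell_step(x_t, state: LstmState, params: LstmLayerParams) -> LstmState:
    """Advance one layer by one time step (see module docstring equations).

    Accepts a single input vector ``(D,)`` with state ``(H,)``, or a batch
    ``(B, D)`` with state ``(B, H)``.
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    h_prev = np.asarray(state.h, dtype=np.float64)
    c_prev = np.asarray(state.c, dtype=np.float64)
    hsz = params.hidden_size
    if x_t.shape[-1] != params.input_size or h_prev.shape[-1] != hsz:
        raise ValueError(
            f"shape mismatch: x has {x_t.shape[-1]} features, state has "
            f"{h_prev.shape[-1]}, layer expects ({params.input_size}, {hsz})"
        )
    z = np.concatenate([h_prev, x_t], axis=-1)
    a = z @ params.W.T + params.b
    i = _sigmoid(a[..., :hsz])
    f = _sigmoid(a[..., hsz : 2 * hsz])
    g = np.tanh(a[..., 2 * hsz : 3 * hsz])
    o = _sigmoid(a[..., 3 * hsz :])
    c = i * g + f * c_prev
    h = o * np.tanh(c)
    return LstmState(h=h, c=c)


def _layer_forward(X, layer: LstmLayerParams, cache: bool = False):
    """Run one layer over a (T, B, D) float32 sequence; returns (T, B, H).

    The input projection for all time steps is done as one matmul; only the
    recurrent term is sequential.
    """
    T, B, _ = X.shape
    H = layer.hidden_size
    W = layer.W.astype(np.float32)
    Wh, Wx = W[:, :H], W[:, H:]
    b = layer.b.astype(np.float32)
    ax = X.reshape(T * B, -1) @ Wx.T
    ax = ax.reshape(T, B, _GATES * H) + b
    Hs = np.zeros((T + 1, B, H), dtype=np.float32)
    caches = []
    c = np.zeros((B, H), dtype=np.float32)
    for t in range(T):
        a = ax[t] + Hs[t] @ Wh.T
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        c_new = i * g + f * c
        tc = np.tanh(c_new)
        Hs[t + 1] = o * tc
        if cache:
            caches.append((i, f, g, o, c, tc))
        c = c_new
    return (Hs, caches) if cache else Hs[1:]


def _layer_backward(X, Hs, caches, layer: LstmLayerParams, dH):
    """BPTT through one layer. ``dH``: (T, B, H) gradients w.r.t. outputs.

    Returns (dX, dW, db).
    """
    T, B, _ = X.shape
    H = layer.hidden_size
    W = layer.W.astype(np.float32)
    Wh, Wx = W[:, :H], W[:, H:]
    dA = np.empty((T, B, _GATES * H), dtype=np.float32)
    dh_next = np.zeros((B, H), dtype=np.float32)
    dc_next = np.zeros((B, H), dtype=np.float32)
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev, tc = caches[t]
        dh = dH[t] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc_next = dc * f
        da = dA[t]
        da[:, :H] = di * i * (1.0 - i)
        da[:, H : 2 * H] = df * f * (1.0 - f)
        da[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
        da[:, 3 * H :] = do * o * (1.0 - o)
        dh_next = da @ Wh
    flat_dA = dA.reshape(T * B, -1)
    dWh = flat_dA.T @ Hs[:-1].reshape(T * B, H)
    dWx = flat_dA.T @ X.reshape(T * B, -1)
    dW = np.concatenate([dWh, dWx], axis=1)
    db = flat_dA.sum(axis=0)
    dX = (flat_dA @ Wx).reshape(X.shape)
    return dX, dW, db


def lstm_encode(signal, params: LstmParams) -> np.ndarray:
    """Encode signal(s) into the top layer's final hidden state.

    ``signal`` may be one sequence ``(T,)`` or a batch ``(B, T)`` of scalar
    time series. Dropout is disabled (inference mode), so the encoding is
    deterministic. Returns ``(feature_size,)`` or ``(B, feature_size)``.
    """
    arr = np.asarray(signal, dtype=np.float32)
    single = arr.ndim == 1
    if single:
        arr = arr[None]
    if arr.ndim != 2:
        raise ValueError("signal must be (T,) or (B, T)")
    X = arr.T[:, :, None]  # (T, B, 1)
    for layer in params.layers:
        X = _layer_forward(X, layer)
    out = X[-1].astype(np.float64)
    return out[0] if single else out


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s, dtype=np.float32) for s in shapes]
        self.v = [np.zeros(s, dtype=np.float32) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def train_lstm_branch(
    X,
    y,
    hidden_sizes: tuple[int, ...] = STAGE1_PRESET["hidden_sizes"],
    dropout: tuple[float, ...] = STAGE1_PRESET["dropout"],
    lr: float = 1e-3,
    epochs: int = 30,
    batch_size: int = 256,
    seed: int = 0,
    clip_norm: float = 5.0,
) -> LstmParams:
    """Train a stacked LSTM with a temporary softmax head; return the params.

    ``X`` is (n, T) scalar sequences, ``y`` class labels. The classification
    head is discarded after training; the per-epoch mean cross-entropy is
    recorded in ``params.loss_history_``. Fully deterministic for a seed.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, T) with one label per row")
    if X.shape[0] == 0:
        raise ValueError("empty training pool")
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("training pool must contain at least 2 classes")
    rng = np.random.default_rng(seed)
    params = init_lstm_params(1, tuple(hidden_sizes), tuple(dropout),
                              seed=int(rng.integers(2**31)))
    n_classes = classes.size
    top = params.feature_size
    head_W = rng.uniform(-0.2, 0.2, size=(n_classes, top)).astype(np.float32)
    head_b = np.zeros(n_classes, dtype=np.float32)
    weights = [l.W.astype(np.float32) for l in params.layers]
    biases = [l.b.astype(np.float32) for l in params.layers]
    flat = weights + biases + [head_W, head_b]
    opt = _Adam([p.shape for p in flat], lr)
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = X[idx].T[:, :, None]  # (T, B, 1)
            yb = y_idx[idx]
            B = len(idx)
            # forward through the stack, caching gate activations
            inputs, hs_all, caches_all, masks = [], [], [], []
            cur = xb
            for li, layer in enumerate(params.layers):
                layer.W, layer.b = weights[li], biases[li]
                inputs.append(cur)
                Hs, caches = _layer_forward(cur, layer, cache=True)
                hs_all.append(Hs)
                caches_all.append(caches)
                out = Hs[1:]
                d = params.dropout[li]
                if d > 0:
                    mask = (rng.random(out.shape) >= d).astype(np.float32) / (1 - d)
                    out = out * mask
                else:
                    mask = None
                masks.append(mask)
                cur = out
            feat = cur[-1]  # (B, top)
            logits = feat @ head_W.T + head_b
            prob = _softmax(logits)
            total += float(-np.log(prob[np.arange(B), yb] + 1e-12).sum())
            # backward
            dlogits = prob
            dlogits[np.arange(B), yb] -= 1.0
            dlogits /= B
            d_head_W = dlogits.T @ feat
            d_head_b = dlogits.sum(axis=0)
            dfeat = dlogits @ head_W
            dH_top = np.zeros_like(cur)
            dH_top[-1] = dfeat
            dH = dH_top
            grads_W = [None] * len(params.layers)
            grads_b = [None] * len(params.layers)
            for li in range(len(params.layers) - 1, -1, -1):
                if masks[li] is not None:
                    dH = dH * masks[li]
                dX, dW, db = _layer_backward(
                    inputs[li], hs_all[li], caches_all[li], params.layers[li], dH
                )
                grads_W[li], grads_b[li] = dW, db
                dH = dX
            grads = grads_W + grads_b + [d_head_W, d_head_b]
            gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if clip_norm and gnorm > clip_norm:
                grads = [g * (clip_norm / gnorm) for g in grads]
            opt.step(flat, grads)
        params.loss_history_.append(total / n)
    for li, layer in enumerate(params.layers):
        layer.W = weights[li].astype(np.float64)
        layer.b = biases[li].astype(np.float64)
    return params


class LstmFeaturizer(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper: fit trains the LSTM branch, transform encodes.

    Parameters mirror :func:`train_lstm_branch`; the Stage I preset (two
    layers, 150 then 100 units, no dropout) is the default, so transformed
    features are 100-dimensional.
    """

    def __init__(
        self,
        hidden_sizes=STAGE1_PRESET["hidden_sizes"],
        dropout=STAGE1_PRESET["dropout"],
        lr=1e-3,
        epochs=30,
        batch_size=256,
        random_state=0,
    ):
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X, y):
        self.params_ = train_lstm_branch(
            X,
            y,
            hidden_sizes=tuple(self.hidden_sizes),
            dropout=tuple(self.dropout),
            lr=self.lr,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.random_state,
        )
        self.loss_history_ = list(self.params_.loss_history_)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "params_")
        return lstm_encode(np.asarray(X), self.params_)
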