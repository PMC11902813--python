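"""Learning primitives: LSTM cell and layers, dense/dropout, Adam, early stop.

Everything here is NumPy.  Forward semantics of the LSTM cell are, per time
step and in this order::

    f_t  = sigmoid(W_f x_t + U_f h_{t-1} + b_f)      (forget gate)
    i_t  = sigmoid(W_i x_t + U_i h_{t-1} + b_i)      (input gate)
    c~_t = tanh   (W_c x_t + U_c h_{t-1} + b_c)      (candidate)
    c_t  = f_t * c_{t-1} + i_t * c~_t                (cell state)
    o_t  = sigmoid(W_o x_t + U_o h_{t-1} + b_o)      (output gate)
    h_t  = o_t * tanh(c_t)                           (hidden state)

with x_t in R^n, h_t, c_t in R^m, W_* in R^{m x n}, U_* in R^{m x m}, and
``*`` the elementwise product.  Training uses exact backpropagation through
time (no truncation) and the Adam optimizer with bias-corrected moment
estimates.  The batched layer implementation stores the four gate blocks
fused in the column order [f | i | o | c~] for speed; the functional
:func:`lstm_cell_step` works on the per-gate matrices directly, and the test
suite pins both to an independent scalar-loop oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "LstmCellParams",
    "LstmState",
    "AdamState",
    "TrainingConfig",
    "lstm_cell_step",
    "lstm_layer_forward",
    "adam_step",
    "early_stopper",
    "dense_forward",
    "dropout_mask",
    "sigmoid",
    "glorot_uniform",
    "orthogonal",
    "Lstm",
    "Dense",
    "TimeDistributedDense",
    "Flatten",
    "Dropout",
    "Sequential",
    "MeanSquaredError",
    "SoftmaxCrossEntropy",
    "Adam",
    "EarlyStopper",
    "fit",
    "TrainingHistory",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically safe logistic; inputs here stay moderate but clip anyway
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random n x n orthogonal matrix (QR of a Gaussian, sign-fixed)."""
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


# ---------------------------------------------------------------------------
# functional ops (spec-level primitives)
# ---------------------------------------------------------------------------


@dataclass
class LstmCellParams:
    """Per-gate LSTM weights: W_* (m x n), U_* (m x m), b_* (m,)."""

    Wf: np.ndarray
    Wi: np.ndarray
    Wc: np.ndarray
    Wo: np.ndarray
    Uf: np.ndarray
    Ui: np.ndarray
    Uc: np.ndarray
    Uo: np.ndarray
    bf: np.ndarray
    bi: np.ndarray
    bc: np.ndarray
    bo: np.ndarray

    def __post_init__(self) -> None:
        m, n = self.Wf.shape
        for name in ("Wf", "Wi", "Wc", "Wo"):
            if getattr(self, name).shape != (m, n):
                raise ValueError(f"{name} must have shape ({m}, {n})")
        for name in ("Uf", "Ui", "Uc", "Uo"):
            if getattr(self, name).shape != (m, m):
                raise ValueError(f"{name} must have shape ({m}, {m})")
        for name in ("bf", "bi", "bc", "bo"):
            if getattr(self, name).shape != (m,):
                raise ValueError(f"{name} must have shape ({m},)")

    @property
    def input_size(self) -> int:
        return self.Wf.shape[1]

    @property
    def hidden_size(self) -> int:
        return self.Wf.shape[0]

    @classmethod
    def zeros(cls, n: int, m: int) -> "LstmCellParams":
        z = lambda *s: np.zeros(s)
        return cls(z(m, n), z(m, n), z(m, n), z(m, n),
                   z(m, m), z(m, m), z(m, m), z(m, m),
                   z(m), z(m), z(m), z(m))


@dataclass
class LstmState:
    """Gate activations and states after one cell step."""

    h: np.ndarray
    c: np.ndarray
    f: np.ndarray
    i: np.ndarray
    c_tilde: np.ndarray
    o: np.ndarray


def lstm_cell_step(params: LstmCellParams, x: np.ndarray,
                   h_prev: np.ndarray, c_prev: np.ndarray) -> LstmState:
    """One LSTM step on vectors, evaluated in the order f, i, c~, c, o, h."""
    x = np.asarray(x, float)
    h_prev = np.asarray(h_prev, float)
    c_prev = np.asarray(c_prev, float)
    if x.shape != (params.input_size,):
        raise ValueError(f"x must have shape ({params.input_size},)")
    if h_prev.shape != (params.hidden_size,):
        raise ValueError(f"h_prev must have shape ({params.hidden_size},)")
    if c_prev.shape != (params.hidden_size,):
        raise ValueError(f"c_prev must have shape ({params.hidden_size},)")
    f = sigmoid(params.Wf @ x + params.Uf @ h_prev + params.bf)
    i = sigmoid(params.Wi @ x + params.Ui @ h_prev + params.bi)
    c_tilde = np.tanh(params.Wc @ x + params.Uc @ h_prev + params.bc)
    c = f * c_prev + i * c_tilde
    o = sigmoid(params.Wo @ x + params.Uo @ h_prev + params.bo)
    h = o * np.tanh(c)
    return LstmState(h=h, c=c, f=f, i=i, c_tilde=c_tilde, o=o)


def lstm_layer_forward(params: LstmCellParams, inputs: np.ndarray,
                       return_sequences: bool = True) -> np.ndarray:
    """Iterate the cell over a (T, n) sequence from h0 = c0 = 0."""
    inputs = np.asarray(inputs, float)
    if inputs.ndim != 2 or inputs.shape[0] == 0:
        raise ValueError("inputs must be a non-empty (T, n) sequence")
    m = params.hidden_size
    h = np.zeros(m)
    c = np.zeros(m)
    outs = np.empty((inputs.shape[0], m))
    for t, x in enumerate(inputs):
        st = lstm_cell_step(params, x, h, c)
        h, c = st.h, st.c
        outs[t] = h
    return outs if return_sequences else outs[-1]


@dataclass
class AdamState:
    """Adam optimizer state for one parameter tensor."""

    theta: np.ndarray
    m: np.ndarray = None  # type: ignore[assignment]
    v: np.ndarray = None  # type: ignore[assignment]
    t: int = 0
    alpha: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.m is None:
            self.m = np.zeros_like(self.theta)
        if self.v is None:
            self.v = np.zeros_like(self.theta)
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta1, beta2 must be in [0, 1)")


def adam_step(state: AdamState, gradient: np.ndarray) -> AdamState:
    """One Adam update (in place on ``state``): moments, bias correction, step."""
    g = np.asarray(gradient, float)
    if g.shape != state.theta.shape:
        raise ValueError("gradient shape must match parameter shape")
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient passed to adam_step")
    state.t += 1
    state.m = state.beta1 * state.m + (1 - state.beta1) * g
    state.v = state.beta2 * state.v + (1 - state.beta2) * g * g
    m_hat = state.m / (1 - state.beta1 ** state.t)
    v_hat = state.v / (1 - state.beta2 ** state.t)
    state.theta -= state.alpha * m_hat / (np.sqrt(v_hat) + state.eps)
    return state


def early_stopper(history: Sequence[float], patience: int,
                  min_delta: float = 0.0) -> tuple[int | None, int]:
    """Apply the early-stopping rule to a loss history.

    Returns ``(stop_epoch, best_epoch)`` with 1-based epochs; ``stop_epoch``
    is ``None`` when training would have run to the end of the history.
    An epoch "improves" when its loss is below the best so far by more than
    ``min_delta``; after ``patience`` consecutive non-improving epochs
    (at least one, so patience 0 stops on the first) training stops.
    """
    if patience < 0:
        raise ValueError("patience must be >= 0")
    best = np.inf
    best_epoch = 0
    wait = 0
    for epoch, loss in enumerate(history, start=1):
        if loss < best - min_delta:
            best = loss
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= max(patience, 1):
                return epoch, best_epoch
    return None, best_epoch


def dense_forward(weights: np.ndarray, bias: np.ndarray, activation: str,
                  inputs: np.ndarray) -> np.ndarray:
    """Affine map plus activation in {relu, softmax, linear}."""
    w = np.asarray(weights, float)
    x = np.asarray(inputs, float)
    if x.shape[-1] != w.shape[0]:
        raise ValueError(
            f"input size {x.shape[-1]} does not match weights {w.shape}"
        )
    z = x @ w + bias
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "softmax":
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)
    if activation == "linear":
        return z
    raise ValueError(f"unknown activation {activation!r}")


def dropout_mask(rate: float, shape: tuple[int, ...],
                 rng: np.random.Generator, training: bool = True) -> np.ndarray:
    """Inverted-dropout multiplier: Bernoulli keep-mask scaled by 1/(1-rate)."""
    if not 0 <= rate < 1:
        raise ValueError("dropout rate must be in [0, 1)")
    if not training or rate == 0.0:
        return np.ones(shape)
    keep = rng.random(shape) >= rate
    return keep.astype(float) / (1.0 - rate)


# ---------------------------------------------------------------------------
# batched layers (training path)
# ---------------------------------------------------------------------------


class Layer:
    """Minimal layer protocol: forward caches, backward returns dX."""

    trainable: bool = True

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Lstm(Layer):
    """Batched LSTM layer over (B, T, n) inputs, h0 = c0 = 0.

    Weights are stored fused: ``W`` is (n, 4m) and ``U`` is (m, 4m) with the
    gate blocks in column order [f | i | o | c~]; ``b`` is (4m,).  Initial
    weights are Glorot-uniform (input), orthogonal per gate (recurrent), and
    zero bias with a unit forget-gate bias.
    """

    def __init__(self, input_size: int, units: int,
                 return_sequences: bool = True,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        n, m = input_size, units
        self.n, self.m = n, m
        self.return_sequences = return_sequences
        self.W = np.concatenate(
            [glorot_uniform(rng, n, m, (n, m)) for _ in range(4)], axis=1)
        self.U = np.concatenate([orthogonal(rng, m) for _ in range(4)], axis=1)
        self.b = np.zeros(4 * m)
        self.b[:m] = 1.0  # unit forget bias
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)
        self._cache: dict[str, np.ndarray] | None = None

    def cell_params(self) -> LstmCellParams:
        """Expose the fused weights as per-gate matrices (views transposed)."""
        m = self.m
        wf, wi, wo, wc = (self.W[:, k * m:(k + 1) * m].T for k in range(4))
        uf, ui, uo, uc = (self.U[:, k * m:(k + 1) * m].T for k in range(4))
        bf, bi, bo, bc = (self.b[k * m:(k + 1) * m] for k in range(4))
        return LstmCellParams(wf, wi, wc, wo, uf, ui, uc, uo, bf, bi, bc, bo)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 3:
            raise ValueError("Lstm expects (batch, time, features) input")
        B, T, n = x.shape
        if n != self.n:
            raise ValueError(f"Lstm input size {n} != expected {self.n}")
        if T == 0:
            raise ValueError("empty sequence")
        m = self.m
        xp = x.reshape(B * T, n) @ self.W
        xp = xp.reshape(B, T, 4 * m)
        h = np.zeros((B, m)); c = np.zeros((B, m))
        U, b = self.U, self.b
        if not training:
            # lean inference path: no per-gate caches (BPTT not needed)
            self._cache = None
            H = np.empty((B, T, m))
            for t in range(T):
                z = xp[:, t] + h @ U + b
                zs = sigmoid(z[:, :3 * m])
                g = np.tanh(z[:, 3 * m:])
                c = zs[:, :m] * c + zs[:, m:2 * m] * g
                h = zs[:, 2 * m:] * np.tanh(c)
                H[:, t] = h
            return H if self.return_sequences else H[:, -1]
        F = np.empty((B, T, m)); I = np.empty((B, T, m))
        O = np.empty((B, T, m)); G = np.empty((B, T, m))
        C = np.empty((B, T, m)); TC = np.empty((B, T, m))
        H = np.empty((B, T, m))
        for t in range(T):
            z = xp[:, t] + h @ U + b
            zs = sigmoid(z[:, :3 * m])
            f = zs[:, :m]; i = zs[:, m:2 * m]; o = zs[:, 2 * m:]
            g = np.tanh(z[:, 3 * m:])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            F[:, t] = f; I[:, t] = i; O[:, t] = o; G[:, t] = g
            C[:, t] = c; TC[:, t] = tc; H[:, t] = h
        self._cache = {"x": x, "F": F, "I": I, "O": O, "G": G,
                       "C": C, "TC": TC, "H": H}
        return H if self.return_sequences else H[:, -1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward before forward")
        cch = self._cache
        x, F, I, O, G, C, TC, H = (cch[k] for k in
                                   ("x", "F", "I", "O", "G", "C", "TC", "H"))
        B, T, m = F.shape
        if self.return_sequences:
            dH = dy
        else:
            dH = np.zeros((B, T, m))
            dH[:, -1] = dy
        dZ = np.empty((B, T, 4 * m))
        dh_rec = np.zeros((B, m))
        dc_rec = np.zeros((B, m))
        Ut = self.U.T
        for t in range(T - 1, -1, -1):
            f = F[:, t]; i = I[:, t]; o = O[:, t]; g = G[:, t]; tc = TC[:, t]
            c_prev = C[:, t - 1] if t > 0 else np.zeros((B, m))
            dh = dH[:, t] + dh_rec
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_rec
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_rec = dc * f
            dz = dZ[:, t]
            dz[:, :m] = df * f * (1.0 - f)
            dz[:, m:2 * m] = di * i * (1.0 - i)
            dz[:, 2 * m:3 * m] = do * o * (1.0 - o)
            dz[:, 3 * m:] = dg * (1.0 - g * g)
            dh_rec = dz @ Ut
        dZ2 = dZ.reshape(B * T, 4 * m)
        self.dW = x.reshape(B * T, self.n).T @ dZ2
        h_prev = np.concatenate([np.zeros((B, 1, m)), H[:, :-1]], axis=1)
        self.dU = h_prev.reshape(B * T, m).T @ dZ2
        self.db = dZ2.sum(axis=0)
        return (dZ2 @ self.W.T).reshape(B, T, self.n)

    def params(self) -> list[np.ndarray]:
        return [self.W, self.U, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.dU, self.db]


class Dense(Layer):
    """Fully connected layer on the last axis, activation in {relu, linear}."""

    def __init__(self, input_size: int, units: int, activation: str = "linear",
                 rng: np.random.Generator | None = None) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        if activation not in ("relu", "linear"):
            raise ValueError("Dense supports relu/linear; softmax lives in the loss")
        self.activation = activation
        self.W = glorot_uniform(rng, input_size, units, (input_size, units))
        self.b = np.zeros(units)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None
        self._z: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[-1] != self.W.shape[0]:
            raise ValueError(
                f"Dense input size {x.shape[-1]} != expected {self.W.shape[0]}")
        self._x = x
        z = x @ self.W + self.b
        self._z = z
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, z = self._x, self._z
        if self.activation == "relu":
            dy = dy * (z > 0)
        flat_x = x.reshape(-1, x.shape[-1])
        flat_dy = dy.reshape(-1, dy.shape[-1])
        self.dW = flat_x.T @ flat_dy
        self.db = flat_dy.sum(axis=0)
        return dy @ self.W.T

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class TimeDistributedDense(Dense):
    """Shared linear map applied at every time step of a (B, T, m) sequence."""


class Flatten(Layer):
    trainable = False

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    trainable = False

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = dropout_mask(self.rate, x.shape, self.rng, training)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sequential:
    """Plain layer stack with forward/backward and a flat parameter list."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    __call__ = forward

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def state_arrays(self) -> list[np.ndarray]:
        return self.params()

    def state_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for p in self.params():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# losses, optimizer wrapper, training loop
# ---------------------------------------------------------------------------


class MeanSquaredError:
    """MSE over every output element; gradient normalized the same way."""

    def value(self, pred: np.ndarray, target: np.ndarray) -> float:
        return float(np.mean((pred - target) ** 2))

    def grad(self, pred: np.ndarray, target: np.ndarray) -> np.ndarray:
        return 2.0 * (pred - target) / pred.size


class SoftmaxCrossEntropy:
    """Categorical cross-entropy with the softmax folded in.

    ``pred`` are logits; ``target`` is one-hot.  The fused gradient
    (softmax(pred) - target) / batch is exact and numerically stable.
    """

    @staticmethod
    def probabilities(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def value(self, pred: np.ndarray, target: np.ndarray) -> float:
        p = self.probabilities(pred)
        eps = 1e-12
        return float(-np.mean(np.sum(target * np.log(p + eps), axis=-1)))

    def grad(self, pred: np.ndarray, target: np.ndarray) -> np.ndarray:
        return (self.probabilities(pred) - target) / pred.shape[0]


class Adam:
    """Adam over a model's parameter list, built on :func:`adam_step`."""

    def __init__(self, params: list[np.ndarray], alpha: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.states = [AdamState(theta=p, alpha=alpha, beta1=beta1,
                                 beta2=beta2, eps=eps) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for state, g in zip(self.states, grads):
            adam_step(state, g)


class EarlyStopper:
    """Streaming form of :func:`early_stopper`."""

    def __init__(self, patience: int, min_delta: float = 0.0) -> None:
        if patience < 0:
            raise ValueError("patience must be >= 0")
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = 0
        self.wait = 0
        self.epoch = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's monitored loss; True means stop now."""
        self.epoch += 1
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_epoch = self.epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= max(self.patience, 1)


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyperparameters (defaults follow the source configuration)."""

    epochs: int = 100
    batch_size: int = 32
    patience: int = 5
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    min_delta: float = 0.0
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch size must be positive")
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int | None = None

    @property
    def monitored(self) -> list[float]:
        return self.val_loss if self.val_loss else self.train_loss


def fit(model: Sequential, x: np.ndarray, y: np.ndarray, loss,
        config: TrainingConfig,
        callback: Callable[[int, float], None] | None = None
        ) -> TrainingHistory:
    """Mini-batch training with Adam and early stopping.

    The early-stopping monitor is the loss on a held-out
    ``validation_fraction`` slice of the training data (when there is enough
    data for at least one validation sample), otherwise the training loss.
    All shuffling is driven by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = x.shape[0]
    n_val = int(np.floor(config.validation_fraction * n))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    x_val, y_val = x[val_idx], y[val_idx]
    x_tr, y_tr = x[train_idx], y[train_idx]
    opt = Adam(model.params(), alpha=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2, eps=config.eps)
    stopper = EarlyStopper(config.patience, config.min_delta)
    history = TrainingHistory()
    n_tr = x_tr.shape[0]
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        for start in range(0, n_tr, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            pred = model.forward(xb, training=True)
            epoch_loss += loss.value(pred, yb) * len(idx)
            model.backward(loss.grad(pred, yb))
            opt.step(model.grads())
        train_loss = epoch_loss / max(n_tr, 1)
        history.train_loss.append(train_loss)
        if n_val:
            pred = model.forward(x_val, training=False)
            monitored = loss.value(pred, y_val)
            history.val_loss.append(monitored)
        else:
            monitored = train_loss
        if callback is not None:
            callback(epoch, monitored)
        if stopper.update(monitored):
            history.stopped_epoch = epoch
            break
    history.best_epoch = stopper.best_epoch
    return history
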