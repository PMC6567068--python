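"""Minimal float32 layer kit for the 1-D time-series classifiers.

Every layer exposes ``forward(x, train)`` and ``backward(dy)``; parameters
and their gradients live in ``params`` / ``grads`` dicts keyed by name so the
optimizer can walk a model generically.  Shapes follow the channels-last
convention: convolutional tensors are ``(batch, length, channels)``.

Only what the voltammogram classifiers need is implemented: stride-1 "same"
1-D convolution, batch normalization, ReLU, global average pooling, dense,
dropout, a single-step LSTM for dimension-shuffled input, and a softmax
attention gate over that input.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1DSame(Layer):
    """Stride-1 'same' 1-D convolution, He-initialized.

    Implemented as im2col plus a single sgemm per pass, which keeps the
    arithmetic in one large BLAS call; the column buffer is cached for the
    weight gradient.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = kernel * c_in
        # He normal: std = sqrt(2 / fan_in)
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (kernel * c_in, c_out)).astype(F32)
        self.params["b"] = np.zeros(c_out, dtype=F32)
        self._pad_l = (kernel - 1) // 2
        self._pad_r = kernel - 1 - self._pad_l
        self._cols: np.ndarray | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, L, _ = x.shape
        xp = np.pad(x, ((0, 0), (self._pad_l, self._pad_r), (0, 0)))
        # (n, L, kernel, c_in) -> (n*L, kernel*c_in)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(n * L, -1)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, L, _ = x.shape
        cols = self._im2col(x)
        self._cols = cols if train else None
        self._shape = (n, L)
        y = cols @ self.params["W"] + self.params["b"]
        return y.reshape(n, L, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, L = self._shape
        flat_dy = dy.reshape(n * L, self.c_out)
        self.grads["W"] = self._cols.T @ flat_dy
        self.grads["b"] = flat_dy.sum(axis=0)
        self._cols = None
        dcols = (flat_dy @ self.params["W"].T).reshape(n, L, self.kernel, self.c_in)
        dxp = np.zeros((n, L + self.kernel - 1, self.c_in), dtype=F32)
        for t in range(self.kernel):
            dxp[:, t : t + L, :] += dcols[:, :, t, :]
        return dxp[:, self._pad_l : self._pad_l + L, :]


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=F32)
        self.params["beta"] = np.zeros(channels, dtype=F32)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(F32)
            self._inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
            self._xhat = ((x - mean) * self._inv).astype(F32)
            return self.params["gamma"] * self._xhat + self.params["beta"]
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.params["gamma"] * ((x - self.running_mean) * inv) + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = tuple(range(dy.ndim - 1))
        m = np.prod([dy.shape[a] for a in axes])
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"]
        dxhat = dy * g
        dx = (
            dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)
        ) * inv
        self._xhat = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, F32(0.0))


class GlobalAvgPool(Layer):
    """(batch, length, channels) -> (batch, channels) mean over length."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :] / F32(self._L), self._L, axis=1)


class Dense(Layer):
    """Affine map, Glorot-uniform initialized."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.params["W"] = rng.uniform(-limit, limit, (d_in, d_out)).astype(F32)
        self.params["b"] = np.zeros(d_out, dtype=F32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        self._x = None
        return dy @ self.params["W"].T


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ShuffledLSTM(Layer):
    """LSTM consuming a dimension-shuffled univariate series.

    The length-L trace is presented as a *single* time step with L features,
    so the recurrence collapses to one cell update from zero state:
    ``c = sigmoid(i) * tanh(g)``, ``h = sigmoid(o) * tanh(c)`` with gate
    pre-activations affine in the input.  (The forget gate acts on the zero
    initial state and so drops out of the computation.)
    """

    def __init__(self, d_in: int, cells: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.cells = cells
        limit = np.sqrt(6.0 / (d_in + 4 * cells))
        self.params["W"] = rng.uniform(-limit, limit, (d_in, 4 * cells)).astype(F32)
        self.params["b"] = np.zeros(4 * cells, dtype=F32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        z = x @ self.params["W"] + self.params["b"]
        H = self.cells
        i, _f, g, o = z[:, :H], z[:, H : 2 * H], z[:, 2 * H : 3 * H], z[:, 3 * H :]
        si, tg, so = _sigmoid(i), np.tanh(g), _sigmoid(o)
        c = si * tg
        tc = np.tanh(c)
        h = so * tc
        if train:
            self._cache = (x, si, tg, so, tc)
        return h.astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, si, tg, so, tc = self._cache
        H = self.cells
        do = dy * tc * so * (1 - so)
        dc = dy * so * (1 - tc * tc)
        di = dc * tg * si * (1 - si)
        dg = dc * si * (1 - tg * tg)
        dz = np.concatenate([di, np.zeros_like(di), dg, do], axis=1).astype(F32)
        self.grads["W"] = x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        self._cache = None
        return dz @ self.params["W"].T


class InputAttention(Layer):
    """Softmax attention over the dimension-shuffled input presentation.

    Produces per-sample nonnegative weights ``a`` summing to 1 over the L
    input positions and emits the reweighted context presentation
    ``x' = L * a * x`` (the factor L keeps the magnitude of an unweighted
    input unchanged under uniform attention).  The weights of the most
    recent forward pass are kept on ``last_attention`` for export.
    """

    def __init__(self, d_in: int, rng: np.random.Generator) -> None:
        super().__init__()
        limit = np.sqrt(6.0 / (2 * d_in))
        self.params["W"] = rng.uniform(-limit, limit, (d_in, d_in)).astype(F32)
        self.params["b"] = np.zeros(d_in, dtype=F32)
        self.last_attention: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        s = x @ self.params["W"] + self.params["b"]
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        a = e / e.sum(axis=1, keepdims=True)
        self.last_attention = a
        L = F32(x.shape[1])
        if train:
            self._cache = (x, a, L)
        return (L * a * x).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, a, L = self._cache
        dx_direct = L * a * dy
        da = L * x * dy
        ds = a * (da - (da * a).sum(axis=1, keepdims=True))
        self.grads["W"] = x.T @ ds
        self.grads["b"] = ds.sum(axis=0)
        self._cache = None
        return (dx_direct + ds @ self.params["W"].T).astype(F32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, y: np.ndarray, sample_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted softmax cross-entropy loss and its gradient w.r.t. logits.

    Loss = sum_i w_i * NLL_i / sum_i w_i; with all weights 1 this is the
    plain mean cross-entropy.
    """
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    w = np.asarray(sample_weights, dtype=np.float64)
    wsum = w.sum()
    nll = -np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = float((w * nll).sum() / wsum)
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits.astype(F32)
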