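"""Minimal NumPy neural-network layers with explicit backpropagation.

Batch-first conventions: temporal tensors are (batch, length, channels),
vector tensors (batch, features).  Every layer caches what its backward pass
needs during ``forward(train=True)``; ``backward`` accumulates parameter
gradients in ``grads`` and returns the gradient w.r.t. its input.

Parameters are created in float64; :meth:`Layer.astype` casts a network to
float32 for speed (training quality is unaffected at these problem sizes,
and gradient-correctness tests run in float64).
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(np.asarray(0.0, dtype=np.result_type(x, np.float32)), x)


def elu(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    out = x.copy()
    neg = x <= 0
    out[neg] = alpha * np.expm1(x[neg])
    return out


class Layer:
    """Base class: parameter/grad dicts plus dtype management."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def astype(self, dtype) -> None:
        for k in self.params:
            self.params[k] = self.params[k].astype(dtype)
        self.zero_grad()


class Conv1D(Layer):
    """Valid (no-padding) strided 1-D convolution, (B, L, Cin) -> (B, L', Cout)."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 stride: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.k = kernel_size
        self.stride = stride
        fan_in = kernel_size * in_channels
        limit = np.sqrt(1.0 / fan_in)
        self.params["W"] = rng.uniform(-limit, limit, size=(fan_in, filters))
        self.params["b"] = np.zeros(filters)
        self.zero_grad()

    @staticmethod
    def output_length(L: int, k: int, stride: int) -> int:
        if L < k:
            raise ValueError(f"input length {L} shorter than kernel {k}")
        return (L - k) // stride + 1

    def _gather(self, x: np.ndarray, Lp: int) -> np.ndarray:
        """im2col by k strided slices: (B, L, Cin) -> (B, Lp, k*Cin)."""
        B, L, Cin = x.shape
        cols = np.empty((B, Lp, self.k, Cin), dtype=x.dtype)
        for j in range(self.k):
            cols[:, :, j, :] = x[:, j : j + self.stride * Lp : self.stride, :]
        return cols.reshape(B, Lp, self.k * Cin)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, L, Cin = x.shape
        Lp = self.output_length(L, self.k, self.stride)
        cols = self._gather(x, Lp)
        if train:
            self._cache = (cols, x.shape)
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        B, Lp, Cout = dy.shape
        Cin = xshape[2]
        self.grads["W"] += cols.reshape(-1, cols.shape[-1]).T @ dy.reshape(-1, Cout)
        self.grads["b"] += dy.sum(axis=(0, 1))
        dcols = (dy @ self.params["W"].T).reshape(B, Lp, self.k, Cin)
        dx = np.zeros(xshape, dtype=dy.dtype)
        for j in range(self.k):  # strided slices; overlap handled by +=
            dx[:, j : j + self.stride * Lp : self.stride, :] += dcols[:, :, j, :]
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over all leading axes.

    Works for (B, L, C) feature maps and (B, F) vectors alike.  Training
    uses batch statistics and updates exponential running estimates;
    inference uses the running estimates.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.zero_grad()

    def astype(self, dtype) -> None:
        super().astype(dtype)
        self.running_mean = self.running_mean.astype(dtype)
        self.running_var = self.running_var.astype(dtype)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(x.dtype)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(x.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        if train:
            self._cache = (xhat, inv_std, axes, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, shape = self._cache
        N = int(np.prod([shape[a] for a in axes]))
        self.grads["gamma"] += (dy * xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"]
        dx = (inv_std / N) * (
            N * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True)
        )
        return dx.astype(dy.dtype, copy=False)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = elu(x, self.alpha)
        if train:
            self._cache = (x > 0, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        pos, y = self._cache
        return dy * np.where(pos, np.asarray(1.0, dtype=dy.dtype), y + self.alpha)


class MaxPool1D(Layer):
    """Temporal max pooling, (B, L, C) -> (B, L // size, C); remainder dropped."""

    def __init__(self, size: int, stride: int | None = None) -> None:
        super().__init__()
        if stride is not None and stride != size:
            raise NotImplementedError("only non-overlapping pooling is supported")
        self.size = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, L, C = x.shape
        Lp = L // self.size
        blocks = x[:, : Lp * self.size, :].reshape(B, Lp, self.size, C)
        arg = blocks.argmax(axis=2)
        if train:
            self._cache = (arg, x.shape, Lp)
        return np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        arg, shape, Lp = self._cache
        B, L, C = shape
        dblocks = np.zeros((B, Lp, self.size, C), dtype=dy.dtype)
        np.put_along_axis(dblocks, arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(shape, dtype=dy.dtype)
        dx[:, : Lp * self.size, :] = dblocks.reshape(B, Lp * self.size, C)
        return dx


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        limit = np.sqrt(1.0 / in_features)
        self.params["W"] = rng.uniform(-limit, limit, size=(in_features, out_features))
        self.params["b"] = np.zeros(out_features)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["W"] += x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        mask = (self.rng.random(x.shape) >= self.rate).astype(x.dtype)
        self._mask = mask / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class LSTM(Layer):
    """Single LSTM layer returning the final short-term state h.

    Input (B, T, D); the hidden/long-term states start at zero for every
    sample (state is per-sample, not carried across the dataset).  Gate
    order in the stacked weight matrices is [input/read r, forget f,
    candidate g, output o].  The recurrent matrix is orthogonally
    initialized and the forget-gate bias starts at 1.
    """

    def __init__(self, input_size: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.units = units
        limit = np.sqrt(1.0 / input_size)
        self.params["Wx"] = rng.uniform(-limit, limit, size=(input_size, 4 * units))
        # orthogonal recurrent blocks, one per gate
        wh = np.zeros((units, 4 * units))
        for g in range(4):
            a = rng.normal(size=(units, units))
            q, _ = np.linalg.qr(a)
            wh[:, g * units : (g + 1) * units] = q
        self.params["Wh"] = wh
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0  # forget gate bias
        self.params["b"] = b
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, D = x.shape
        n = self.units
        h = np.zeros((B, n), dtype=x.dtype)
        c = np.zeros((B, n), dtype=x.dtype)
        # project the whole input sequence in one matmul
        xproj = x.reshape(B * T, D) @ self.params["Wx"] + self.params["b"]
        xproj = xproj.reshape(B, T, 4 * n)
        cache = []
        for t in range(T):
            z = xproj[:, t, :] + h @ self.params["Wh"]
            gates = np.empty_like(z)
            gates[:, : 2 * n] = _sigmoid(z[:, : 2 * n])
            gates[:, 2 * n : 3 * n] = np.tanh(z[:, 2 * n : 3 * n])
            gates[:, 3 * n :] = _sigmoid(z[:, 3 * n :])
            r = gates[:, :n]
            f = gates[:, n : 2 * n]
            g = gates[:, 2 * n : 3 * n]
            o = gates[:, 3 * n :]
            c_new = f * c + r * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if train:
                cache.append((h, c, gates, tc))
            h, c = h_new, c_new
        if train:
            self._cache = (cache, x)
        return h

    def backward(self, dh_final: np.ndarray) -> np.ndarray:
        cache, x = self._cache
        B, T, D = x.shape
        n = self.units
        dz_all = np.empty((B, T, 4 * n), dtype=dh_final.dtype)
        dh = dh_final.copy()
        dc = np.zeros((B, n), dtype=dh_final.dtype)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, gates, tc = cache[t]
            r = gates[:, :n]
            f = gates[:, n : 2 * n]
            g = gates[:, 2 * n : 3 * n]
            o = gates[:, 3 * n :]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            dz = dz_all[:, t, :]
            dz[:, :n] = (dc * g) * r * (1 - r)
            dz[:, n : 2 * n] = (dc * c_prev) * f * (1 - f)
            dz[:, 2 * n : 3 * n] = (dc * r) * (1 - g**2)
            dz[:, 3 * n :] = do * o * (1 - o)
            self.grads["Wh"] += h_prev.T @ dz
            dh = dz @ self.params["Wh"].T
            dc = dc * f
        flat = dz_all.reshape(B * T, 4 * n)
        self.grads["Wx"] += x.reshape(B * T, D).T @ flat
        self.grads["b"] += flat.sum(axis=0)
        return (flat @ self.params["Wx"].T).reshape(B, T, D)
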