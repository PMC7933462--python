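"""Minimal NumPy neural-network layers with hand-written backprop.

Just enough machinery for the two models in this package: 3x3 valid
convolutions (im2col), dense layers, ReLU, inverted dropout, zero
padding, and an unrolled LSTM.  Layers cache what their backward pass
needs; parameters live in ``layer.params`` with matching
``layer.grads``, and a layer with ``trainable = False`` is skipped by
the optimizers (freezing).

Everything is float32 and seeded explicitly; gradients are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    trainable = True

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ZeroPad2D(Layer):
    """Pad the two spatial axes of (N, H, W, C) with zeros."""

    def __init__(self, pad: int = 1):
        super().__init__()
        self.pad = pad

    def forward(self, x, train=False):
        p = self.pad
        return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))

    def backward(self, dout):
        p = self.pad
        return dout[:, p:-p, p:-p, :]


class Conv2D(Layer):
    """Valid k x k convolution on (N, H, W, C_in) -> (N, H-k+1, W-k+1, C_out)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.k = kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = kernel * kernel * in_ch
        w = glorot(rng, (fan_in, out_ch), fan_in, out_ch)
        b = np.zeros(out_ch, dtype=F32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def _im2col(self, x):
        k = self.k
        v = sliding_window_view(x, (k, k), axis=(1, 2))  # (N, Ho, Wo, C, k, k)
        v = v.transpose(0, 1, 2, 4, 5, 3)  # (N, Ho, Wo, k, k, C)
        return np.ascontiguousarray(v).reshape(v.shape[:3] + (-1,))

    def forward(self, x, train=False):
        cols = self._im2col(x.astype(F32, copy=False))
        if train:
            self._cache = (x.shape, cols)
        return cols @ self.params[0] + self.params[1]

    def backward(self, dout):
        x_shape, cols = self._cache
        w, _ = self.params
        n, ho, wo, _ = dout.shape
        dout2 = dout.reshape(-1, self.out_ch)
        self.grads[0][...] = cols.reshape(-1, cols.shape[-1]).T @ dout2
        self.grads[1][...] = dout2.sum(axis=0)
        dcols = (dout2 @ w.T).reshape(n, ho, wo, self.k, self.k, self.in_ch)
        dx = np.zeros(x_shape, dtype=F32)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i:i + ho, j:j + wo, :] += dcols[:, :, :, i, j, :]
        return dx


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        w = glorot(rng, (in_dim, out_dim), in_dim, out_dim)
        b = np.zeros(out_dim, dtype=F32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train=False):
        x = x.astype(F32, copy=False)
        if train:
            self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.params[0].T


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout: identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class LSTM(Layer):
    """Unrolled LSTM over (N, T, D) -> (N, T, H) hidden sequences.

    Gate order i, f, g, o; forget-gate bias initialized to 1.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.in_dim, self.hidden = in_dim, hidden
        wx = glorot(rng, (in_dim, 4 * hidden), in_dim, hidden)
        wh = glorot(rng, (hidden, 4 * hidden), hidden, hidden)
        b = np.zeros(4 * hidden, dtype=F32)
        b[hidden:2 * hidden] = 1.0
        self.params = [wx, wh, b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=False):
        wx, wh, b = self.params
        n, t, _ = x.shape
        h = self.hidden
        hs = np.zeros((n, t, h), dtype=F32)
        h_t = np.zeros((n, h), dtype=F32)
        c_t = np.zeros((n, h), dtype=F32)
        cache = []
        x = x.astype(F32, copy=False)
        for step in range(t):
            z = x[:, step, :] @ wx + h_t @ wh + b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            c_prev = c_t
            c_t = f * c_prev + i * g
            tanh_c = np.tanh(c_t)
            if train:
                cache.append((h_t.copy(), c_prev, i, f, g, o, tanh_c, x[:, step, :]))
            h_t = o * tanh_c
            hs[:, step, :] = h_t
        if train:
            self._cache = cache
        return hs

    def backward(self, dout):
        wx, wh, b = self.params
        for g in self.grads:
            g[...] = 0
        cache = self._cache
        n, t, h = dout.shape
        dx = np.zeros((n, t, self.in_dim), dtype=F32)
        dh_next = np.zeros((n, h), dtype=F32)
        dc_next = np.zeros((n, h), dtype=F32)
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g_, o, tanh_c, x_t = cache[step]
            dh = dout[:, step, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c ** 2) + dc_next
            di = dc * g_
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g_ ** 2),
                do * o * (1 - o),
            ], axis=1)
            self.grads[0] += x_t.T @ dz
            self.grads[1] += h_prev.T @ dz
            self.grads[2] += dz.sum(axis=0)
            dx[:, step, :] = dz @ wx.T
            dh_next = dz @ wh.T
            dc_next = dc * f
        return dx


class LastStep(Layer):
    """Select the final time step of an (N, T, H) sequence."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, dout):
        dx = np.zeros(self._shape, dtype=F32)
        dx[:, -1, :] = dout
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def trainable_parameters(self):
        for layer in self.layers:
            if layer.trainable:
                yield from zip(layer.params, layer.grads)

    def all_parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


sigmoid = _sigmoid


def bce_sum(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    """Binary cross-entropy summed over the batch, probabilities clipped to [eps, 1-eps]."""
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum())


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, model: Sequential, lr: float, momentum: float = 0.0):
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self._vel: dict[int, np.ndarray] = {}

    def step(self):
        for p, g in self.model.trainable_parameters():
            v = self._vel.setdefault(id(p), np.zeros_like(p))
            v *= self.momentum
            v -= self.lr * g
            p += v


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def step(self):
        self._t += 1
        for p, g in self.model.trainable_parameters():
            m = self._m.setdefault(id(p), np.zeros_like(p))
            v = self._v.setdefault(id(p), np.zeros_like(p))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self._t)
            vh = v / (1 - self.b2 ** self._t)
            p -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(p.dtype)


def numerical_gradient(f, param: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central finite differences of scalar-valued ``f`` w.r.t. ``param`` (in place)."""
    grad = np.zeros_like(param, dtype=np.float64)
    it = np.nditer(param, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = param[idx]
        param[idx] = orig + eps
        hi = f()
        param[idx] = orig - eps
        lo = f()
        param[idx] = orig
        grad[idx] = (hi - lo) / (2 * eps)
        it.iternext()
    return grad
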