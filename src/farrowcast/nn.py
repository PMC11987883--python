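"""Minimal CPU neural-network layers with hand-written backpropagation.

Everything the farrowing-time regressor needs — 1-D convolution, batch
normalization, ELU, dropout, LSTM, the position-aware time-weighted
self-attention layer, linear heads and Adam — implemented directly on NumPy
arrays.  All activations flow as ``(batch, time, channels)`` tensors.  Every
layer exposes ``forward(x, train=...)`` / ``backward(dout)`` and keeps its
parameters and gradients in ``params`` / ``grads`` dicts so the optimizer
can walk a whole model uniformly.  Correctness of the analytic gradients is
pinned by finite-difference checks in the test suite.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

__all__ = [
    "Layer", "Conv1d", "BatchNorm1d", "ELU", "Dropout", "LSTM",
    "PTWSA", "Linear", "MeanPoolTime", "LastStepPool", "Sequential", "Adam",
    "softmax",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Row-wise softmax, shifted for numerical stability."""
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameter/gradient dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Conv1d(Layer):
    """Length-preserving 1-D convolution over the time axis.

    Odd kernel with symmetric zero padding, so the output sequence length
    always equals the input length.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd and positive, got {kernel_size}")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size
        self.params["W"] = _glorot(rng, c_in * kernel_size, c_out, (kernel_size * c_in, c_out))
        self.params["b"] = np.zeros(c_out)
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, t, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        # (B, t, c_in, k) -> (B, t, k, c_in) -> (B, t, k*c_in)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        patches = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, t, self.k * self.c_in)
        self._cache = (patches, x.shape)
        return patches @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        patches, (B, t, c) = self._cache
        self.grads["W"] += patches.reshape(-1, self.k * self.c_in).T @ dout.reshape(-1, self.c_out)
        self.grads["b"] += dout.sum(axis=(0, 1))
        dpatch = (dout @ self.params["W"].T).reshape(B, t, self.k, self.c_in)
        p = self.k // 2
        dxp = np.zeros((B, t + 2 * p, self.c_in))
        for j in range(self.k):
            dxp[:, j : j + t, :] += dpatch[:, :, j, :]
        return dxp[:, p : p + t, :]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over the (batch, time) axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        self._cache = (x, xhat, mu, std, train)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, xhat, mu, std, train = self._cache
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 1))
        self.grads["beta"] += dout.sum(axis=(0, 1))
        dxhat = dout * self.params["gamma"]
        if not train:
            return dxhat / std
        m = x.shape[0] * x.shape[1]
        dvar = (dxhat * (x - mu)).sum(axis=(0, 1)) * (-0.5) / std**3
        dmu = -dxhat.sum(axis=(0, 1)) / std + dvar * (-2.0) * (x - mu).mean(axis=(0, 1))
        return dxhat / std + dvar * 2.0 * (x - mu) / m + dmu / m


class ELU(Layer):
    """Exponential linear unit, alpha = 1."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
        self._cache = (x, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, out = self._cache
        return dout * np.where(x > 0, 1.0, out + 1.0)


class Dropout(Layer):
    """Inverted dropout: active in training mode only."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class LSTM(Layer):
    """Single-layer LSTM returning the full hidden-state sequence.

    Gate layout in the fused weight matrices is (input, forget, cell,
    output); the forget-gate bias starts at 1 so early training does not
    wash out the cell state.
    """

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.d = c_in, hidden
        self.params["Wx"] = _glorot(rng, c_in, 4 * hidden, (c_in, 4 * hidden))
        self.params["Wh"] = _glorot(rng, hidden, 4 * hidden, (hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0
        self.params["b"] = b
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, t, c = x.shape
        d = self.d
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, d))
        cst = np.zeros((B, d))
        H = np.empty((B, t, d))
        caches = []
        for s in range(t):
            xt = x[:, s, :]
            z = xt @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :d])
            f = _sigmoid(z[:, d : 2 * d])
            g = np.tanh(z[:, 2 * d : 3 * d])
            o = _sigmoid(z[:, 3 * d :])
            c_new = f * cst + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            caches.append((xt, h, cst, i, f, g, o, tc))
            h, cst = h_new, c_new
            H[:, s, :] = h
        self._cache = (caches, x.shape)
        return H

    def backward(self, dout: np.ndarray) -> np.ndarray:
        caches, (B, t, c) = self._cache
        d = self.d
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx, dWh, db = self.grads["Wx"], self.grads["Wh"], self.grads["b"]
        dx = np.zeros((B, t, c))
        dh_next = np.zeros((B, d))
        dc_next = np.zeros((B, d))
        for s in range(t - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tc = caches[s]
            dh = dout[:, s, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc**2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dWx += xt.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, s, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        return dx


class PTWSA(Layer):
    """Position-aware time-weighted self-attention.

    A learnable positional-encoding matrix ``P`` (t x d) is added to the
    hidden-state sequence; queries, keys and values come from learned d x d
    projections; each key row i is rescaled by the learnable time weight
    ``w_time[i]`` before scoring, letting training up-weight time steps near
    the event.  Attention scores are divided by sqrt(d) by default (the
    literal ``d`` divisor is available via ``scale_mode='d'``) and softmaxed
    row-wise, so every attention row sums to one.
    """

    def __init__(self, t: int, d: int, rng: np.random.Generator, scale_mode: str = "sqrt_d"):
        super().__init__()
        if scale_mode not in ("sqrt_d", "d"):
            raise ValueError(f"scale_mode must be 'sqrt_d' or 'd', got {scale_mode!r}")
        self.t, self.d = t, d
        self.scale = math.sqrt(d) if scale_mode == "sqrt_d" else float(d)
        self.params["P"] = rng.normal(0.0, 0.02, size=(t, d))
        self.params["Wq"] = _glorot(rng, d, d, (d, d))
        self.params["Wk"] = _glorot(rng, d, d, (d, d))
        self.params["Wv"] = _glorot(rng, d, d, (d, d))
        self.params["w_time"] = np.ones(t)
        self.zero_grads()
        self.last_attention: np.ndarray | None = None

    def forward(self, H: np.ndarray, train: bool = False) -> np.ndarray:
        B, t, d = H.shape
        if (t, d) != (self.t, self.d):
            raise ValueError(f"expected input (B, {self.t}, {self.d}), got {H.shape}")
        P, Wq, Wk, Wv, w = (self.params[k] for k in ("P", "Wq", "Wk", "Wv", "w_time"))
        if not all(np.isfinite(p).all() for p in self.params.values()):
            raise FloatingPointError("PTW-SA parameters contain non-finite values")
        Hp = H + P
        Q, K, V = Hp @ Wq, Hp @ Wk, Hp @ Wv
        Kp = K * w[None, :, None]
        S = Q @ Kp.transpose(0, 2, 1) / self.scale
        A = softmax(S, axis=-1)
        O = A @ V
        self.last_attention = A
        self._cache = (Hp, Q, K, V, Kp, A)
        return O

    def backward(self, dO: np.ndarray) -> np.ndarray:
        Hp, Q, K, V, Kp, A = self._cache
        Wq, Wk, Wv, w = (self.params[k] for k in ("Wq", "Wk", "Wv", "w_time"))
        dA = dO @ V.transpose(0, 2, 1)
        dV = A.transpose(0, 2, 1) @ dO
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQ = dS @ Kp / self.scale
        dKp = dS.transpose(0, 2, 1) @ Q / self.scale
        dK = dKp * w[None, :, None]
        self.grads["w_time"] += (dKp * K).sum(axis=(0, 2))
        self.grads["Wq"] += np.einsum("bti,btj->ij", Hp, dQ)
        self.grads["Wk"] += np.einsum("bti,btj->ij", Hp, dK)
        self.grads["Wv"] += np.einsum("bti,btj->ij", Hp, dV)
        dHp = dQ @ Wq.T + dK @ Wk.T + dV @ Wv.T
        self.grads["P"] += dHp.sum(axis=0)
        return dHp


class Linear(Layer):
    """Affine map over the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        self.params["W"] = _glorot(rng, d_in, d_out, (d_in, d_out))
        self.params["b"] = np.zeros(d_out)
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["W"] += x.reshape(-1, self.d_in).T @ dout.reshape(-1, self.d_out)
        self.grads["b"] += dout.reshape(-1, self.d_out).sum(axis=0)
        return dout @ self.params["W"].T


class MeanPoolTime(Layer):
    """Mean over the time axis: (B, t, d) -> (B, d)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, None, :], self._t, axis=1) / self._t


class LastStepPool(Layer):
    """Keep only the final time step: (B, t, d) -> (B, d)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape)
        dx[:, -1, :] = dout
        return dx


class Sequential(Layer):
    """Forward/backward composition of layers."""

    def __init__(self, layers: Iterable[Layer]):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def parameter_layers(self) -> list[Layer]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.parameter_layers())
            elif layer.params:
                out.append(layer)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for l in self.parameter_layers() for p in l.params.values())


class Adam:
    """Adam optimizer over the parameter layers of a model."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[li][k] = self.b1 * self.m[li][k] + (1 - self.b1) * g
                self.v[li][k] = self.b2 * self.v[li][k] + (1 - self.b2) * g * g
                mhat = self.m[li][k] / bc1
                vhat = self.v[li][k] / bc2
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
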