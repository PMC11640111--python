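"""Minimal numpy layers for 1-D sequence networks.

All layers operate on arrays of shape ``(batch, time, channels)`` unless
noted otherwise, expose ``forward``/``backward`` with cached activations,
and hold their parameters and gradients in dicts so an optimizer can
update them in place.  Backward passes are verified against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: parameter-free identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1D(Layer):
    """1-D convolution along the time axis via im2col.

    padding="valid" shortens the sequence by kernel-1; "same" zero-pads
    so the output length equals the input length (odd kernels).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 padding: str = "valid", rng: np.random.Generator | None = None):
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.padding = padding
        fan_in = kernel * in_channels
        self.params = {
            "W": _he_init(rng, fan_in, (fan_in, out_channels)),
            "b": np.zeros(out_channels),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.padding == "valid":
            return x
        left = (self.kernel - 1) // 2
        right = self.kernel - 1 - left
        return np.pad(x, ((0, 0), (left, right), (0, 0)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = self._pad(x)
        B, T, C = xp.shape
        k = self.kernel
        # (B, T_out, k, C): sliding windows over time
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        win = np.ascontiguousarray(np.swapaxes(win, 2, 3))
        self._cols = win.reshape(B, T - k + 1, k * C)
        self._x_shape = x.shape
        return self._cols @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T_out, _ = dout.shape
        k, C = self.kernel, self.in_channels
        cols2 = self._cols.reshape(-1, k * C)
        dout2 = dout.reshape(-1, self.out_channels)
        self.grads["W"][...] = cols2.T @ dout2
        self.grads["b"][...] = dout2.sum(axis=0)
        dcols = (dout2 @ self.params["W"].T).reshape(B, T_out, k, C)
        T_pad = T_out + k - 1
        dxp = np.zeros((B, T_pad, C))
        for j in range(k):
            dxp[:, j:j + T_out, :] += dcols[:, :, j, :]
        if self.padding == "same":
            left = (k - 1) // 2
            dxp = dxp[:, left:left + self._x_shape[1], :]
        return dxp


class Dense(Layer):
    """Affine map on the last axis."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": _he_init(rng, in_dim, (in_dim, out_dim)),
            "b": np.zeros(out_dim),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.grads["W"][...] = x2.T @ d2
        self.grads["b"][...] = d2.sum(axis=0)
        return (dout @ self.params["W"].T).reshape(self._x.shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * (1.0 - self._y ** 2)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Reshape(Layer):
    """Reshape the per-sample part to ``shape`` (batch axis preserved)."""

    def __init__(self, shape: tuple):
        super().__init__()
        self.shape = shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; requires T divisible by pool."""

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        p = self.pool
        if T % p:
            raise ValueError(f"sequence length {T} not divisible by pool {p}")
        xr = x.reshape(B, T // p, p, C)
        self._argmax = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T_out, C = dout.shape
        p = self.pool
        dxr = np.zeros((B, T_out, p, C))
        b, t, c = np.indices((B, T_out, C))
        dxr[b, t, self._argmax, c] = dout
        return dxr.reshape(self._in_shape)


class Upsample1D(Layer):
    """Nearest-neighbour repetition along time by an integer factor."""

    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(x, self.factor, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, C = dout.shape
        f = self.factor
        return dout.reshape(B, T // f, f, C).sum(axis=2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class LSTM(Layer):
    """Single LSTM layer with full backpropagation through time.

    Gate order in the fused weight matrix is (input, forget, cell, output).
    The forget-gate bias starts at 1 — the usual trick to keep memory open
    early in training.  ``return_sequences=False`` emits only the final
    hidden state, shape (batch, hidden).
    """

    def __init__(self, in_dim: int, hidden: int, return_sequences: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_dim = in_dim
        self.hidden = hidden
        self.return_sequences = return_sequences
        scale = 1.0 / np.sqrt(in_dim + hidden)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.params = {
            "W": rng.uniform(-scale, scale, size=(in_dim + hidden, 4 * hidden)),
            "b": b,
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        W, b = self.params["W"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        self._x = x
        hs = np.empty((B, T, H))
        for t in range(T):
            z = np.concatenate([x[:, t, :], h], axis=1)
            gates = z @ W + b
            i = _sigmoid(gates[:, :H])
            f = _sigmoid(gates[:, H:2 * H])
            g = np.tanh(gates[:, 2 * H:3 * H])
            o = _sigmoid(gates[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t, :] = h
            self._cache.append((z, i, f, g, o, c_prev, tc))
        self._hs = hs
        return hs if self.return_sequences else hs[:, -1, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, _ = x.shape
        H = self.hidden
        W = self.params["W"]
        dW = np.zeros_like(W)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            z, i, f, g, o, c_prev, tc = self._cache[t]
            if self.return_sequences:
                dh = dout[:, t, :] + dh_next
            else:
                dh = (dout if t == T - 1 else 0.0) + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dgates = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ], axis=1)
            dW += z.T @ dgates
            db += dgates.sum(axis=0)
            dz = dgates @ W.T
            dx[:, t, :] = dz[:, :self.in_dim]
            dh_next = dz[:, self.in_dim:]
        self.grads["W"][...] = dW
        self.grads["b"][...] = db
        return dx
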