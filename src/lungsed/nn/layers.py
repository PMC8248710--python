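"""Layers with explicit forward/backward passes (float32 throughout).

Weight layouts follow the TensorFlow/Keras conventions so that trainable
parameter counts are directly comparable with models built there:

* ``Dense``: kernel (D, U) + bias (U,).
* ``LSTM``: input kernel (D, 4H), recurrent kernel (H, 4H), single bias
  (4H,); gate order i, f, c, o; forget-gate bias initialized to 1.
* ``GRU``: input kernel (D, 3H), recurrent kernel (H, 3H) and *separate*
  input/recurrent biases (2, 3H) (the ``reset_after`` formulation, which
  is what CuDNN-compatible GRUs use); gate order z, r, n.
* ``ConvFront``: channels-last 2-D convolutions with 'same' padding.

Sequences are batched as (B, T, D).  All matmul-heavy work (input
projections, kernel gradients) is hoisted out of the timestep loop.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

DTYPE = np.float32


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base: parameters and gradients are dicts of same-keyed arrays."""

    def params(self) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def grads(self) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params().values())


class Dense(Layer):
    """Time-distributed fully connected layer on the last axis."""

    def __init__(self, n_in: int, n_out: int, activation: str = "linear",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if activation not in ("linear", "relu"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.activation = activation
        self.W = _glorot(rng, (n_in, n_out))
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x):
        self._x = x
        y = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = y > 0
            y = y * self._mask
        return y

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self._mask
        x2 = self._x.reshape(-1, self.W.shape[0])
        d2 = dy.reshape(-1, self.W.shape[1])
        self.dW[...] = x2.T @ d2
        self.db[...] = d2.sum(axis=0)
        return dy @ self.W.T


class LSTM(Layer):
    """Unidirectional LSTM over (B, T, D) -> (B, T, H)."""

    def __init__(self, n_in: int, n_units: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        H = n_units
        self.H = H
        self.Wx = _glorot(rng, (n_in, 4 * H))
        self.Wh = _glorot(rng, (H, 4 * H))
        self.b = np.zeros(4 * H, dtype=DTYPE)
        self.b[H:2 * H] = 1.0  # forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def grads(self):
        return {"Wx": self.dWx, "Wh": self.dWh, "b": self.db}

    def forward(self, x):
        B, T, D = x.shape
        H = self.H
        self._x = x
        xp = (x.reshape(-1, D) @ self.Wx + self.b).reshape(B, T, 4 * H)
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        hs = np.empty((B, T, H), dtype=DTYPE)
        cache = []
        for t in range(T):
            g = xp[:, t] + h @ self.Wh
            i = _sigmoid(g[:, :H])
            f = _sigmoid(g[:, H:2 * H])
            gc = np.tanh(g[:, 2 * H:3 * H])
            o = _sigmoid(g[:, 3 * H:])
            c_new = f * c + i * gc
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((h, c, i, f, gc, o, tanh_c))
            h, c = h_new, c_new
            hs[:, t] = h
        self._cache = cache
        return hs

    def backward(self, dy):
        B, T, H = dy.shape
        D = self.Wx.shape[0]
        dXP = np.empty((B, T, 4 * H), dtype=DTYPE)
        self.dWh[...] = 0.0
        dh = np.zeros((B, H), dtype=DTYPE)
        dc = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, gc, o, tanh_c = self._cache[t]
            dht = dy[:, t] + dh
            do = dht * tanh_c * o * (1 - o)
            dct = dc + dht * o * (1 - tanh_c**2)
            di = dct * gc * i * (1 - i)
            df = dct * c_prev * f * (1 - f)
            dgc = dct * i * (1 - gc**2)
            dgates = np.concatenate([di, df, dgc, do], axis=1)
            dXP[:, t] = dgates
            self.dWh += h_prev.T @ dgates
            dh = dgates @ self.Wh.T
            dc = dct * f
        d2 = dXP.reshape(-1, 4 * H)
        self.dWx[...] = self._x.reshape(-1, D).T @ d2
        self.db[...] = d2.sum(axis=0)
        return (d2 @ self.Wx.T).reshape(B, T, D)


class GRU(Layer):
    """Unidirectional GRU (reset_after form) over (B, T, D) -> (B, T, H)."""

    def __init__(self, n_in: int, n_units: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        H = n_units
        self.H = H
        self.Wx = _glorot(rng, (n_in, 3 * H))
        self.Wh = _glorot(rng, (H, 3 * H))
        self.bx = np.zeros(3 * H, dtype=DTYPE)
        self.bh = np.zeros(3 * H, dtype=DTYPE)
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.dbx = np.zeros_like(self.bx)
        self.dbh = np.zeros_like(self.bh)

    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "bx": self.bx, "bh": self.bh}

    def grads(self):
        return {"Wx": self.dWx, "Wh": self.dWh, "bx": self.dbx, "bh": self.dbh}

    def forward(self, x):
        B, T, D = x.shape
        H = self.H
        self._x = x
        xp = (x.reshape(-1, D) @ self.Wx + self.bx).reshape(B, T, 3 * H)
        h = np.zeros((B, H), dtype=DTYPE)
        hs = np.empty((B, T, H), dtype=DTYPE)
        cache = []
        for t in range(T):
            hp = h @ self.Wh + self.bh
            z = _sigmoid(xp[:, t, :H] + hp[:, :H])
            r = _sigmoid(xp[:, t, H:2 * H] + hp[:, H:2 * H])
            n = np.tanh(xp[:, t, 2 * H:] + r * hp[:, 2 * H:])
            h_new = z * h + (1 - z) * n
            cache.append((h, z, r, n, hp[:, 2 * H:]))
            h = h_new
            hs[:, t] = h
        self._cache = cache
        return hs

    def backward(self, dy):
        B, T, H = dy.shape
        D = self.Wx.shape[0]
        dXP = np.empty((B, T, 3 * H), dtype=DTYPE)
        self.dWh[...] = 0.0
        self.dbh[...] = 0.0
        dh = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            h_prev, z, r, n, hp_n = self._cache[t]
            dht = dy[:, t] + dh
            dz = dht * (h_prev - n) * z * (1 - z)
            dn = dht * (1 - z)
            dpre_n = dn * (1 - n**2)
            dr = dpre_n * hp_n * r * (1 - r)
            dhp = np.concatenate([dz, dr, dpre_n * r], axis=1)
            dXP[:, t] = np.concatenate([dz, dr, dpre_n], axis=1)
            self.dWh += h_prev.T @ dhp
            self.dbh += dhp.sum(axis=0)
            dh = dht * z + dhp @ self.Wh.T
        d2 = dXP.reshape(-1, 3 * H)
        self.dWx[...] = self._x.reshape(-1, D).T @ d2
        self.dbx[...] = d2.sum(axis=0)
        return (d2 @ self.Wx.T).reshape(B, T, D)


class Bidirectional(Layer):
    """Concatenates a forward and a time-reversed recurrent pass."""

    def __init__(self, forward_layer: Layer, backward_layer: Layer):
        self.fwd = forward_layer
        self.bwd = backward_layer

    def params(self):
        out = {f"fwd.{k}": v for k, v in self.fwd.params().items()}
        out.update({f"bwd.{k}": v for k, v in self.bwd.params().items()})
        return out

    def grads(self):
        out = {f"fwd.{k}": v for k, v in self.fwd.grads().items()}
        out.update({f"bwd.{k}": v for k, v in self.bwd.grads().items()})
        return out

    def forward(self, x):
        yf = self.fwd.forward(x)
        yb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([yf, yb], axis=2)

    def backward(self, dy):
        H = dy.shape[2] // 2
        dxf = self.fwd.backward(np.ascontiguousarray(dy[:, :, :H]))
        dxb = self.bwd.backward(np.ascontiguousarray(dy[:, ::-1, H:]))[:, ::-1]
        return dxf + dxb


class _Conv2D:
    """Channels-last 'same'-padded convolution with stride, via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 stride: tuple[int, int], rng: np.random.Generator):
        kt, kf = kernel
        self.kernel = kernel
        self.stride = stride
        fan_in, fan_out = kt * kf * c_in, c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, size=(kt * kf * c_in, c_out)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.c_in = c_in
        self.c_out = c_out

    @staticmethod
    def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
        out = -(-n // s)  # ceil
        total = max((out - 1) * s + k - n, 0)
        return out, total // 2, total - total // 2

    def forward(self, x):
        # x: (B, T, F, C)
        B, T, F, C = x.shape
        kt, kf = self.kernel
        st, sf = self.stride
        T_out, pt0, pt1 = self._same_pad(T, kt, st)
        F_out, pf0, pf1 = self._same_pad(F, kf, sf)
        xp = np.pad(x, ((0, 0), (pt0, pt1), (pf0, pf1), (0, 0)))
        view = np.lib.stride_tricks.sliding_window_view(xp, (kt, kf), axis=(1, 2))
        # view: (B, T_p-kt+1, F_p-kf+1, C, kt, kf)
        col = view[:, ::st, ::sf][:, :T_out, :F_out]
        col = np.ascontiguousarray(col.transpose(0, 1, 2, 4, 5, 3))  # (..., kt, kf, C)
        self._col_shape = col.shape
        col2 = col.reshape(-1, kt * kf * C)
        y = (col2 @ self.W + self.b).reshape(B, T_out, F_out, self.c_out)
        self._col2 = col2
        self._x_shape = x.shape
        self._pads = (pt0, pt1, pf0, pf1)
        self._mask = y > 0
        return y * self._mask  # relu

    def backward(self, dy):
        dy = dy * self._mask
        B, T_out, F_out, _ = dy.shape
        kt, kf = self.kernel
        st, sf = self.stride
        d2 = dy.reshape(-1, self.c_out)
        self.dW[...] = self._col2.T @ d2
        self.db[...] = d2.sum(axis=0)
        dcol = (d2 @ self.W.T).reshape(B, T_out, F_out, kt, kf, self.c_in)
        Bx, T, F, C = self._x_shape
        pt0, pt1, pf0, pf1 = self._pads
        dxp = np.zeros((B, T + pt0 + pt1, F + pf0 + pf1, C), dtype=DTYPE)
        ti = np.arange(T_out) * st
        fi = np.arange(F_out) * sf
        for a in range(kt):
            for b in range(kf):
                dxp[:, ti[:, None] + a, fi[None, :] + b, :] += dcol[:, :, :, a, b, :]
        return dxp[:, pt0:pt0 + T, pf0:pf0 + F, :]


class ConvFront(Layer):
    """CNN front end: halves the time axis (938 -> 469) and re-embeds frames.

    Two 3x3 'same' convolutions (1 -> 16 -> 64 channels, ReLU), the
    second with stride 2 on both axes, then per-frame flattening of
    channels x reduced-frequency into a feature vector.  For the
    standard 938 x 193 input this yields 469 frames of 64 x 97 = 6,208
    features.
    """

    def __init__(self, n_features: int, rng: np.random.Generator | None = None,
                 channels: tuple[int, int] = (16, 64)):
        rng = rng or np.random.default_rng(0)
        c1, c2 = channels
        self.conv1 = _Conv2D(1, c1, (3, 3), (1, 1), rng)
        self.conv2 = _Conv2D(c1, c2, (3, 3), (2, 2), rng)
        self.n_out = c2 * (-(-n_features // 2))

    def params(self):
        return {"conv1.W": self.conv1.W, "conv1.b": self.conv1.b,
                "conv2.W": self.conv2.W, "conv2.b": self.conv2.b}

    def grads(self):
        return {"conv1.W": self.conv1.dW, "conv1.b": self.conv1.db,
                "conv2.W": self.conv2.dW, "conv2.b": self.conv2.db}

    def forward(self, x):
        # (B, T, D) -> (B, T, D, 1) -> conv -> (B, T/2, D/2, C) -> flatten
        h = self.conv1.forward(x[..., None])
        h = self.conv2.forward(h)
        B, T2, F2, C = h.shape
        self._h_shape = h.shape
        return h.reshape(B, T2, F2 * C)

    def backward(self, dy):
        dh = dy.reshape(self._h_shape)
        dh = self.conv2.backward(dh)
        dx = self.conv1.backward(dh)
        return dx[..., 0]


class SequenceModel:
    """A feed-forward chain of layers mapping (B, T, D) to per-frame logits."""

    def __init__(self, layers: list[Layer], meta: dict | None = None):
        self.layers = layers
        self.meta = dict(meta or {})

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            h = layer.forward(h)
        return h[..., 0]  # (B, T_out)

    def backward(self, dlogits: np.ndarray) -> None:
        d = np.asarray(dlogits, dtype=DTYPE)[..., None]
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def scores(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(self.forward(x))

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                out[f"l{i}.{k}"] = v
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.grads().items():
                out[f"l{i}.{k}"] = v
        return out

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params().values())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        params = self.params()
        if set(weights) != set(params):
            raise ValueError("weight keys do not match model parameters")
        for k, v in params.items():
            v[...] = weights[k]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params())
        path.with_suffix(".json").write_text(json.dumps(self.meta, indent=2))
        return path.with_suffix(".npz")

    def load_weights(self, path: str | Path) -> None:
        with np.load(Path(path)) as data:
            self.set_weights({k: data[k] for k in data.files})
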