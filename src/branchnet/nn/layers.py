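"""Layers with explicit forward/backward passes.

Conventions
-----------
* 3-D activations are ``(batch, length, channels)``; 2-D are ``(batch, features)``.
* ``forward(x, training=...)`` caches whatever ``backward`` needs; ``backward(dy)``
  returns ``dx`` and accumulates parameter gradients in ``self.grads`` (aligned
  with ``self.params``).
* All weights are initialised from a shared ``numpy.random.Generator`` so that a
  fixed seed yields bit-identical parameters.
"""

from __future__ import annotations

import numpy as np


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class Layer:
    """Base class; parameter-free layers keep empty ``params``/``grads``."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x, training: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0


class Dense(Layer):
    """Affine map ``y = x W + b`` on 2-D input. Activation is a separate layer."""

    def __init__(self, in_features: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.W = glorot_uniform(rng, (in_features, units), in_features, units)
        self.b = np.zeros(units)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0] += self._x.T @ dy
        self.grads[1] += dy.sum(axis=0)
        return dy @ self.W.T


class Conv1D(Layer):
    """1-D convolution, stride 1, 'same' padding.

    Weight shape is ``(kernel, in_channels, filters)``; padding puts
    ``(kernel - 1) // 2`` positions on the left so output length equals input
    length for both odd and even kernels.
    """

    def __init__(self, in_channels: int, filters: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        self.kernel_size = kernel_size
        fan_in = kernel_size * in_channels
        self.W = glorot_uniform(rng, (kernel_size, in_channels, filters), fan_in, filters)
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.pad_left = (kernel_size - 1) // 2
        self.pad_right = kernel_size // 2

    def forward(self, x, training=False):
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        # windows: (batch, length, channels, kernel)
        windows = np.lib.stride_tricks.sliding_window_view(xp, self.kernel_size, axis=1)
        self._windows = windows
        self._in_shape = x.shape
        return np.einsum("blck,kcf->blf", windows, self.W) + self.b

    def backward(self, dy):
        self.grads[0] += np.einsum("blck,blf->kcf", self._windows, dy)
        self.grads[1] += dy.sum(axis=(0, 1))
        B, L, C = self._in_shape
        dxp = np.zeros((B, L + self.pad_left + self.pad_right, C))
        contrib = np.einsum("blf,kcf->bklc", dy, self.W)
        for k in range(self.kernel_size):
            dxp[:, k : k + L, :] += contrib[:, k]
        return dxp[:, self.pad_left : self.pad_left + L, :]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Flatten(Layer):
    """Collapse trailing axes; identity on already-2-D input."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape3D(Layer):
    """Lift a 2-D ``(batch, d)`` activation to ``(batch, d, 1)`` so a recurrent
    layer can consume it (used when a recurrent layer opens the common section)."""

    def forward(self, x, training=False):
        return x[:, :, None]

    def backward(self, dy):
        return dy[:, :, 0]


class Dropout(Layer):
    """Inverted dropout; active only while training. Draws its mask from the
    network-owned generator so runs are reproducible."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class BatchNorm(Layer):
    """Batch normalisation over the batch (and length, for 3-D input) axis,
    one (gamma, beta) pair per channel. Inference uses running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))  # (0,) for 2-D, (0, 1) for 3-D
        self._training = training
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._n = x.size // x.shape[-1]
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.grads[0] += (dy * self._xhat).sum(axis=axes)
        self.grads[1] += dy.sum(axis=axes)
        if not self._training:
            return dy * self.gamma / self._std
        n = self._n
        dxhat = dy * self.gamma
        return (dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std


class GRU(Layer):
    """Gated recurrent unit over ``(batch, length, channels)``.

    Update convention: ``h_t = z_t * h_{t-1} + (1 - z_t) * htilde_t`` with the
    reset gate applied to the previous state inside the candidate.
    """

    def __init__(self, in_channels: int, units: int, rng: np.random.Generator, return_sequences: bool = True):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        C, U = in_channels, units
        self.Wx = glorot_uniform(rng, (C, 3 * U), C, U)   # input kernels  [z | r | h]
        self.Wh = glorot_uniform(rng, (U, 3 * U), U, U)   # recurrent kernels
        self.b = np.zeros(3 * U)
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training=False):
        B, L, _ = x.shape
        U = self.units
        h = np.zeros((B, U))
        xs = x @ self.Wx + self.b  # (B, L, 3U)
        self._cache = []
        out = np.empty((B, L, U))
        for t in range(L):
            z = sigmoid(xs[:, t, :U] + h @ self.Wh[:, :U])
            r = sigmoid(xs[:, t, U : 2 * U] + h @ self.Wh[:, U : 2 * U])
            rh = r * h
            htilde = np.tanh(xs[:, t, 2 * U :] + rh @ self.Wh[:, 2 * U :])
            h_new = z * h + (1 - z) * htilde
            self._cache.append((h, z, r, rh, htilde))
            h = h_new
            out[:, t] = h
        self._x = x
        return out if self.return_sequences else out[:, -1]

    def backward(self, dy):
        x = self._x
        B, L, C = x.shape
        U = self.units
        dWx, dWh, db = self.grads
        dx = np.zeros_like(x)
        dh = np.zeros((B, U))
        for t in range(L - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dy[:, t]
            elif t == L - 1:
                dh = dh + dy
            h_prev, z, r, rh, htilde = self._cache[t]
            dhtilde = dh * (1 - z)
            dz = dh * (h_prev - htilde)
            da_h = dhtilde * (1 - htilde ** 2)          # pre-tanh
            da_z = dz * z * (1 - z)
            drh = da_h @ self.Wh[:, 2 * U :].T
            dr = drh * h_prev
            da_r = dr * r * (1 - r)
            da = np.concatenate([da_z, da_r, da_h], axis=1)  # (B, 3U)
            dWx_t = x[:, t].T @ da
            dWx += dWx_t
            db += da.sum(axis=0)
            dWh[:, :U] += h_prev.T @ da_z
            dWh[:, U : 2 * U] += h_prev.T @ da_r
            dWh[:, 2 * U :] += rh.T @ da_h
            dx[:, t] = da @ self.Wx.T
            dh = (
                dh * z
                + da_z @ self.Wh[:, :U].T
                + da_r @ self.Wh[:, U : 2 * U].T
                + drh * r
            )
        return dx


class LSTM(Layer):
    """Long short-term memory layer over ``(batch, length, channels)``."""

    def __init__(self, in_channels: int, units: int, rng: np.random.Generator, return_sequences: bool = True):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        C, U = in_channels, units
        self.Wx = glorot_uniform(rng, (C, 4 * U), C, U)   # [i | f | g | o]
        self.Wh = glorot_uniform(rng, (U, 4 * U), U, U)
        self.b = np.zeros(4 * U)
        self.b[U : 2 * U] = 1.0  # forget-gate bias at 1, the usual stabiliser
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training=False):
        B, L, _ = x.shape
        U = self.units
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        xs = x @ self.Wx + self.b
        self._cache = []
        out = np.empty((B, L, U))
        for t in range(L):
            a = xs[:, t] + h @ self.Wh
            i = sigmoid(a[:, :U])
            f = sigmoid(a[:, U : 2 * U])
            g = np.tanh(a[:, 2 * U : 3 * U])
            o = sigmoid(a[:, 3 * U :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            out[:, t] = h
        self._x = x
        return out if self.return_sequences else out[:, -1]

    def backward(self, dy):
        x = self._x
        B, L, C = x.shape
        U = self.units
        dWx, dWh, db = self.grads
        dx = np.zeros_like(x)
        dh = np.zeros((B, U))
        dc = np.zeros((B, U))
        for t in range(L - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dy[:, t]
            elif t == L - 1:
                dh = dh + dy
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
                axis=1,
            )
            dWx += x[:, t].T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, t] = da @ self.Wx.T
            dh = da @ self.Wh.T
            dc = dc * f
        return dx


class Bidirectional(Layer):
    """Run a forward and a backward copy of a recurrent layer and concatenate.

    With ``return_sequences=False`` the forward cell contributes its last-step
    output and the backward cell the output of its own last step, i.e. the
    original first time point.
    """

    def __init__(self, fwd: Layer, bwd: Layer):
        super().__init__()
        self.return_sequences = fwd.return_sequences
        fwd.return_sequences = True
        bwd.return_sequences = True
        self.fwd = fwd
        self.bwd = bwd
        self.params = fwd.params + bwd.params
        self.grads = fwd.grads + bwd.grads

    def forward(self, x, training=False):
        yf = self.fwd.forward(x, training)
        yb = self.bwd.forward(x[:, ::-1], training)[:, ::-1]
        self._units = yf.shape[-1]
        if self.return_sequences:
            return np.concatenate([yf, yb], axis=-1)
        return np.concatenate([yf[:, -1], yb[:, 0]], axis=-1)

    def backward(self, dy):
        U = self._units
        L = self.fwd._x.shape[1]
        if self.return_sequences:
            dyf, dyb = dy[..., :U], dy[..., U:]
        else:
            B = dy.shape[0]
            dyf = np.zeros((B, L, U))
            dyb = np.zeros((B, L, U))
            dyf[:, -1] = dy[:, :U]
            dyb[:, 0] = dy[:, U:]
        dxf = self.fwd.backward(dyf)
        dxb = self.bwd.backward(dyb[:, ::-1])[:, ::-1]
        return dxf + dxb


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers
        self.params = [p for layer in layers for p in layer.params]
        self.grads = [g for layer in layers for g in layer.grads]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
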