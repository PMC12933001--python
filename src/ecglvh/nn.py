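"""Minimal neural-network building blocks (numpy, CPU).

Implements exactly the layer set the iLVM network needs — 1-D convolution,
batch normalization, ReLU, max-pooling, dropout, global average pooling and
dense layers — with hand-written backward passes and an Adam optimizer.
Everything is float32 and deterministic given the seeded generators passed in;
there is no global random state.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: parameters/gradients as dicts, optional input gradient."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grad(self):
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


class Conv1d(Layer):
    """Stride-1 'same' convolution over (N, C, L) arrays."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.in_channels, self.out_channels, self.kernel = in_channels, out_channels, kernel
        std = np.sqrt(2.0 / (in_channels * kernel))
        self.params["W"] = rng.normal(0, std, (out_channels, in_channels, kernel)).astype(DTYPE)
        self.params["b"] = np.zeros(out_channels, dtype=DTYPE)
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel // 2
        self._xp = None

    def forward(self, x, training=False, rng=None):
        W, b = self.params["W"], self.params["b"]
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        self._xp = xp
        L = x.shape[2]
        out = np.zeros((x.shape[0], self.out_channels, L), dtype=DTYPE)
        for i in range(self.kernel):
            # (F, N, L) contribution of kernel tap i
            out += np.tensordot(W[:, :, i], xp[:, :, i : i + L], axes=([1], [1])
                                ).transpose(1, 0, 2)
        return out + b[None, :, None]

    def backward(self, dout):
        W = self.params["W"]
        xp = self._xp
        L = dout.shape[2]
        self.grads["b"] = dout.sum(axis=(0, 2))
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for i in range(self.kernel):
            dW[:, :, i] = np.tensordot(dout, xp[:, :, i : i + L], axes=([0, 2], [0, 2]))
            dxp[:, :, i : i + L] += np.tensordot(
                W[:, :, i], dout, axes=([0], [1])
            ).transpose(1, 0, 2)
        self.grads["W"] = dW
        end = dxp.shape[2] - self.pad_right
        return dxp[:, :, self.pad_left : end]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (N, C, L)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self.update_stats = True
        self._cache = None

    def forward(self, x, training=False, rng=None):
        gamma, beta = self.params["gamma"], self.params["beta"]
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            if self.update_stats:
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mean).astype(DTYPE)
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std.astype(DTYPE), training)
        return (gamma[None, :, None] * xhat + beta[None, :, None]).astype(DTYPE)

    def backward(self, dout):
        xhat, inv_std, training = self._cache
        gamma = self.params["gamma"]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dout.sum(axis=(0, 2))
        dxhat = dout * gamma[None, :, None]
        if not training:
            return dxhat * inv_std[None, :, None]
        m = dout.shape[0] * dout.shape[2]
        term = (m * dxhat
                - dxhat.sum(axis=(0, 2), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True))
        return (inv_std[None, :, None] / m) * term


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1d(Layer):
    """Kernel 2, stride 2; odd trailing sample is dropped."""

    def forward(self, x, training=False, rng=None):
        n, c, L = x.shape
        self._in_length = L
        L2 = L // 2
        xr = x[:, :, : 2 * L2].reshape(n, c, L2, 2)
        self._argmax = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._argmax[..., None], axis=3)[..., 0]

    def backward(self, dout):
        n, c, L2 = dout.shape
        dxr = np.zeros((n, c, L2, 2), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=3)
        dx = np.zeros((n, c, self._in_length), dtype=dout.dtype)
        dx[:, :, : 2 * L2] = dxr.reshape(n, c, 2 * L2)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p).astype(DTYPE) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class GlobalAveragePool(Layer):
    """Mean over the time axis: (N, C, L) -> (N, C)."""

    def forward(self, x, training=False, rng=None):
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        return np.repeat(dout[:, :, None], self._length, axis=2) / self._length


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.params["W"] = rng.normal(0, std, (in_features, out_features)).astype(DTYPE)
        self.params["b"] = np.zeros(out_features, dtype=DTYPE)
        self._x = None

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Adam:
    """Adam with optional L2 weight decay added to the gradient.

    ``param_refs`` is a list of (name, layer, key) triples; only those
    parameters are updated, which is how layer freezing is implemented.
    """

    def __init__(self, param_refs, lr=5e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.param_refs = list(param_refs)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {name: np.zeros_like(layer.params[key])
                   for name, layer, key in self.param_refs}
        self._v = {name: np.zeros_like(layer.params[key])
                   for name, layer, key in self.param_refs}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for name, layer, key in self.param_refs:
            g = layer.grads[key]
            if self.weight_decay:
                g = g + self.weight_decay * layer.params[key]
            m = self._m[name] = b1 * self._m[name] + (1 - b1) * g
            v = self._v[name] = b2 * self._v[name] + (1 - b2) * (g * g)
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            layer.params[key] = (layer.params[key] - self.lr * update).astype(DTYPE)
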