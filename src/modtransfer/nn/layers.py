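"""Minimal neural-network layers on numpy.

One-dimensional convolutional stacks are all this package needs: every
network here (single-channel modality classifier, per-channel branches of
the multichannel classifier, variational-autoencoder encoder/decoder) is a
pipeline of Conv1D / MaxPool1D / Flatten / Dense / BatchNorm1d / Softmax.

Conventions
-----------
* Temporal tensors are ``(N, C, L)`` — batch, channels, time samples.
* Dense inputs are ``(N, F)``.
* ``forward(x, training=...)`` caches what ``backward`` needs; ``backward``
  consumes the most recent forward pass and accumulates parameter gradients
  in ``self.grads`` while returning the gradient w.r.t. the layer input.
* All parameters live in ``self.params`` (name -> ndarray) so that
  optimizers, checkpoints and weight transfer can treat layers uniformly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "glorot_uniform",
    "Layer",
    "Conv1D",
    "MaxPool1D",
    "Flatten",
    "Reshape",
    "Dense",
    "BatchNorm1d",
    "Softmax",
    "Upsample1D",
]


def glorot_uniform(shape, fan_in, fan_out, rng):
    """Glorot/Xavier uniform draw on [-sqrt(6/(fan_in+fan_out)), +...]."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _apply_activation(z, activation):
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "linear":
        return z
    raise ValueError(f"unknown activation {activation!r}")


def _activation_grad(grad, z, activation):
    if activation == "relu":
        return grad * (z > 0)
    if activation == "linear":
        return grad
    raise ValueError(f"unknown activation {activation!r}")


class Layer:
    """Base layer: parameter-free, shape-preserving identity."""

    def __init__(self, name=""):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grads(self):
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def __repr__(self):
        return f"{type(self).__name__}({self.name})"


class Conv1D(Layer):
    """1-D convolution (cross-correlation), stride 1.

    ``padding='valid'`` shrinks the sequence by ``kernel_size - 1``;
    ``padding='full'`` grows it by the same amount (used by the mirrored
    VAE decoder to invert a valid convolution exactly).
    """

    def __init__(self, in_channels, out_channels, kernel_size, activation="relu",
                 padding="valid", name="conv", rng=None):
        super().__init__(name)
        if padding not in ("valid", "full"):
            raise ValueError(f"unknown padding {padding!r}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = int(kernel_size)
        self.stride = 1
        self.activation = activation
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * self.kernel_size
        fan_out = out_channels * self.kernel_size
        self.params = {
            "W": glorot_uniform((out_channels, in_channels, self.kernel_size),
                                fan_in, fan_out, rng),
            "b": np.zeros(out_channels),
        }
        self.zero_grads()

    def output_length(self, L):
        if self.padding == "valid":
            return L - self.kernel_size + 1
        return L + self.kernel_size - 1

    def forward(self, x, training=False):
        K = self.kernel_size
        if self.padding == "full":
            x = np.pad(x, ((0, 0), (0, 0), (K - 1, K - 1)))
        if x.shape[2] < K:
            raise ValueError(
                f"layer {self.name}: input length {x.shape[2]} < kernel {K}")
        win = sliding_window_view(x, K, axis=2)  # (N, Cin, Lout, K)
        z = np.einsum("nclk,ock->nol", win, self.params["W"], optimize=True)
        z += self.params["b"][None, :, None]
        self._win = win
        self._z = z
        return _apply_activation(z, self.activation)

    def backward(self, grad):
        K = self.kernel_size
        g = _activation_grad(grad, self._z, self.activation)
        self.grads["W"] += np.einsum("nclk,nol->ock", self._win, g, optimize=True)
        self.grads["b"] += g.sum(axis=(0, 2))
        gpad = np.pad(g, ((0, 0), (0, 0), (K - 1, K - 1)))
        gwin = sliding_window_view(gpad, K, axis=2)  # (N, Cout, Lin(+pad), K)
        Wflip = self.params["W"][:, :, ::-1]
        dx = np.einsum("notk,ock->nct", gwin, Wflip, optimize=True)
        if self.padding == "full":
            dx = dx[:, :, K - 1:-(K - 1)]
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling; trailing samples that do not fill a
    window are dropped (and receive zero gradient)."""

    def __init__(self, pool_size=2, name="pool"):
        super().__init__(name)
        self.pool_size = int(pool_size)

    def output_length(self, L):
        return L // self.pool_size

    def forward(self, x, training=False):
        p = self.pool_size
        N, C, L = x.shape
        Lout = L // p
        self._in_shape = x.shape
        xr = x[:, :, : Lout * p].reshape(N, C, Lout, p)
        self._argmax = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, grad):
        p = self.pool_size
        N, C, L = self._in_shape
        Lout = grad.shape[2]
        dxr = np.zeros((N, C, Lout, p))
        n, c, t = np.ogrid[:N, :C, :Lout]
        dxr[n, c, t, self._argmax] = grad
        dx = np.zeros(self._in_shape)
        dx[:, :, : Lout * p] = dxr.reshape(N, C, Lout * p)
        return dx


class Flatten(Layer):
    def __init__(self, name="flatten"):
        super().__init__(name)

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Reshape(Layer):
    def __init__(self, shape, name="reshape"):
        super().__init__(name)
        self.shape = tuple(shape)

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_features, out_features, activation="linear",
                 name="dense", rng=None):
        super().__init__(name)
        self.in_features = in_features
        self.out_features = out_features
        self.activation = activation
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": glorot_uniform((out_features, in_features),
                                in_features, out_features, rng),
            "b": np.zeros(out_features),
        }
        self.zero_grads()

    def forward(self, x, training=False):
        self._x = x
        z = x @ self.params["W"].T + self.params["b"]
        self._z = z
        return _apply_activation(z, self.activation)

    def backward(self, grad):
        g = _activation_grad(grad, self._z, self.activation)
        self.grads["W"] += g.T @ self._x
        self.grads["b"] += g.sum(axis=0)
        return g @ self.params["W"]


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over ``(N, C, L)`` input.

    Used as the input-facing regularisation layer of every network here;
    its parameters are never part of a weight transfer.
    """

    def __init__(self, num_features, momentum=0.99, eps=1e-3, name="bn"):
        super().__init__(name)
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(num_features),
            "beta": np.zeros(num_features),
        }
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.zero_grads()

    def forward(self, x, training=False):
        self._training = training
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        return (self.params["gamma"][None, :, None] * self._xhat
                + self.params["beta"][None, :, None])

    def backward(self, grad):
        gamma = self.params["gamma"]
        self.grads["gamma"] += (grad * self._xhat).sum(axis=(0, 2))
        self.grads["beta"] += grad.sum(axis=(0, 2))
        gxhat = grad * gamma[None, :, None]
        if not self._training:
            return gxhat / self._std[None, :, None]
        # batch statistics participate in the normalisation
        N, C, L = grad.shape
        m = N * L
        s1 = gxhat.sum(axis=(0, 2))[None, :, None]
        s2 = (gxhat * self._xhat).sum(axis=(0, 2))[None, :, None]
        return (gxhat - s1 / m - self._xhat * s2 / m) / self._std[None, :, None]


class Softmax(Layer):
    """Row-wise softmax over ``(N, C)`` with exact backward pass, so that
    gradients of class *probabilities* (not logits) w.r.t. the input are
    available for Jacobian saliency."""

    def __init__(self, name="softmax"):
        super().__init__(name)

    def forward(self, x, training=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, grad):
        p = self._p
        return p * (grad - (grad * p).sum(axis=1, keepdims=True))


class Upsample1D(Layer):
    """Nearest-neighbour upsampling by an integer factor, then zero-pad or
    crop to ``target_length`` (inverts a floor-division pooling length)."""

    def __init__(self, factor, target_length, name="upsample"):
        super().__init__(name)
        self.factor = int(factor)
        self.target_length = int(target_length)

    def forward(self, x, training=False):
        self._in_len = x.shape[2]
        y = np.repeat(x, self.factor, axis=2)
        Lt = self.target_length
        if y.shape[2] < Lt:
            y = np.pad(y, ((0, 0), (0, 0), (0, Lt - y.shape[2])))
        elif y.shape[2] > Lt:
            y = y[:, :, :Lt]
        return y

    def backward(self, grad):
        full = self._in_len * self.factor
        if grad.shape[2] < full:
            grad = np.pad(grad, ((0, 0), (0, 0), (0, full - grad.shape[2])))
        else:
            grad = grad[:, :, :full]
        N, C, _ = grad.shape
        return grad.reshape(N, C, self._in_len, self.factor).sum(axis=3)
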