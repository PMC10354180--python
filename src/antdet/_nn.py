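"""Minimal NumPy neural-network engine for small dense-prediction models.

Implements exactly the pieces the detectors need: 2-D convolution (same
padding, optional dilation) via im2col + BLAS matmul, batch normalization,
ReLU, 2x2 max-pooling, 2x nearest-neighbour upsampling, channel
concatenation, the Adam optimizer, and a per-pixel softmax cross-entropy
loss with optional class weights and per-sample masking. Forward/backward
passes are explicit (no autograd); every layer caches what its backward
pass needs. All layers are gradient-checked against central finite
differences in the test suite.

Activations and parameters default to float32; float64 is available for
numerical checks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Upsample2d",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy_loss_grad",
]


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution with 'same' zero padding and optional dilation.

    He-normal weight init; the caller supplies the RNG so model construction
    is deterministic given a seed.
    """

    def __init__(self, in_channels, out_channels, kernel_size=3, dilation=1,
                 rng=None, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng()
        k = int(kernel_size)
        fan_in = in_channels * k * k
        std = np.sqrt(2.0 / fan_in)
        self.W = Parameter(rng.normal(0.0, std, (out_channels, in_channels, k, k)).astype(dtype))
        self.b = Parameter(np.zeros(out_channels, dtype=dtype))
        self.k = k
        self.dilation = int(dilation)
        self._cache = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, train):
        k, d = self.k, self.dilation
        pad = d * (k // 2)
        B, C, H, W = x.shape
        cout = self.W.value.shape[0]
        if pad:
            xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        else:
            xp = x
        if k == 1:
            cols = x.transpose(0, 2, 3, 1).reshape(B * H * W, C)
        else:
            span = (k - 1) * d + 1
            win = sliding_window_view(xp, (span, span), axis=(2, 3))[..., ::d, ::d]
            cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
                B * H * W, C * k * k)
        out = cols @ self.W.value.reshape(cout, -1).T
        out += self.b.value
        self._cache = (cols, (B, C, H, W))
        return np.ascontiguousarray(out.reshape(B, H, W, cout).transpose(0, 3, 1, 2))

    def backward(self, grad):
        cols, (B, C, H, W) = self._cache
        k, d = self.k, self.dilation
        pad = d * (k // 2)
        cout = self.W.value.shape[0]
        gmat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(B * H * W, cout)
        self.W.grad += (gmat.T @ cols).reshape(self.W.value.shape)
        self.b.grad += gmat.sum(axis=0)
        dcols = gmat @ self.W.value.reshape(cout, -1)
        if k == 1:
            return np.ascontiguousarray(
                dcols.reshape(B, H, W, C).transpose(0, 3, 1, 2))
        dcols = dcols.reshape(B, H, W, C, k, k)
        dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i * d:i * d + H, j * d:j * d + W] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2))
        if pad:
            return np.ascontiguousarray(dxp[:, :, pad:pad + H, pad:pad + W])
        return dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype)
        else:
            mu = self.running_mean
            var = self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv, train = self._cache
        dgamma = (grad * xhat).sum(axis=(0, 2, 3))
        dbeta = grad.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[None, :, None, None] * inv[None, :, None, None]
        if not train:
            return grad * g
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        return g * (grad
                    - dbeta[None, :, None, None] / n
                    - xhat * dgamma[None, :, None, None] / n)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0)


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2 (spatial dims must be even)."""

    def forward(self, x, train):
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(B, C, H // 2, W // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (B, C, H, W))
        return out

    def backward(self, grad):
        idx, (B, C, H, W) = self._cache
        dxr = np.zeros((B, C, H // 2, W // 2, 4), dtype=grad.dtype)
        np.put_along_axis(dxr, idx[..., None], grad[..., None], axis=-1)
        dxr = dxr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dxr).reshape(B, C, H, W)


class Upsample2d(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x, train):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        B, C, H, W = grad.shape
        return grad.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam with a mutable learning rate (for the two-phase schedule)."""

    def __init__(self, params: list[Parameter], lr=5e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def softmax(scores: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax."""
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_loss_grad(scores, labels, class_weights=None, sample_mask=None):
    """Mean per-pixel softmax cross-entropy and its gradient w.r.t. scores.

    Parameters
    ----------
    scores : (B, C, H, W) raw class scores.
    labels : (B, H, W) integer class map in [0, C).
    class_weights : optional (C,) per-class loss weights; the loss is the
        weighted mean (normalized by the summed weights).
    sample_mask : optional (B,) boolean; samples with False contribute
        nothing to loss or gradient (used by the two-head trainer). The
        normalization still counts the full batch, so each *sample* keeps
        the same weight regardless of how the batch splits across heads —
        the two head losses then sum to the batch-mean objective.

    Returns
    -------
    loss : float
    grad : (B, C, H, W) d loss / d scores
    """
    B, C, H, W = scores.shape
    p = softmax(scores, axis=1)
    onehot_idx = labels[:, None, :, :]
    py = np.take_along_axis(p, onehot_idx, axis=1)[:, 0]
    logpy = np.log(np.clip(py, 1e-12, None))
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=scores.dtype)[labels]
    else:
        w = np.ones((B, H, W), dtype=scores.dtype)
    norm = w.sum()
    if sample_mask is not None:
        w = w * np.asarray(sample_mask, dtype=scores.dtype)[:, None, None]
    if norm <= 0 or w.sum() <= 0:
        return 0.0, np.zeros_like(scores)
    loss = -(w * logpy).sum() / norm
    grad = p.copy()
    np.put_along_axis(grad, onehot_idx,
                      np.take_along_axis(grad, onehot_idx, axis=1) - 1.0, axis=1)
    grad *= (w / norm)[:, None, :, :]
    return float(loss), grad
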