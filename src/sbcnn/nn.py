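"""Minimal NumPy engine for binarization-aware training.

Implements exactly the pieces a stochastic binarized CNN needs: conv /
linear layers with real-valued shadow weights binarized on the forward
pass (sign) and updated through the straight-through estimator, batch
normalization, sign activations with the hard-tanh STE window, max
pooling, presentation aggregation, softmax cross-entropy and Adam.

Compute is float32 through single large BLAS GEMMs (im2col keeps patches
in a (features, batch*locations) layout so each convolution is one
matmul); a seed-fixed single-threaded run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DTYPE = np.float32


@dataclass
class Param:
    data: np.ndarray
    grad: np.ndarray = field(init=False)
    clip: bool = False  # clip to [-1, 1] after each update (shadow weights)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)


def _sign(x: np.ndarray) -> np.ndarray:
    """sign with the package-wide sign(0) = +1 convention."""
    return np.where(x >= 0, DTYPE(1.0), DTYPE(-1.0))


def im2col(x: np.ndarray, k: int, stride: int, pad: int, pad_value: float = 0.0):
    """(B, C, H, W) -> (C*k*k, B*L) patch matrix plus output dims.

    Binarized convolutions pad with -1 (not 0) so every input stays in
    {-1, +1} and the XNOR-popcount identity holds at the borders.
    """
    if pad:
        x = np.pad(
            x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=pad_value
        )
    B, C, H, W = x.shape
    out_h = (H - k) // stride + 1
    out_w = (W - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, C, out_h, out_w, k, k)
    cols = win.transpose(1, 4, 5, 0, 2, 3).reshape(C * k * k, B * out_h * out_w)
    return np.ascontiguousarray(cols), out_h, out_w


def col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col` (scatter-add of patch gradients)."""
    B, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    out_h = (Hp - k) // stride + 1
    out_w = (Wp - k) // stride + 1
    dcols = dcols.reshape(C, k, k, B, out_h, out_w)
    dxp = np.zeros((B, C, Hp, Wp), dtype=dcols.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + stride * out_h : stride, kj : kj + stride * out_w : stride] += (
                dcols[:, ki, kj].transpose(1, 0, 2, 3)
            )
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class BinConv2d(Layer):
    """2-D convolution with optionally binarized weights.

    ``binary=True`` uses sign(W) on the forward pass; the gradient is
    passed straight through to the shadow weights, which the optimizer
    clips to [-1, 1].
    """

    def __init__(self, in_ch, out_ch, k, stride=1, pad=0, binary=True, rng=None):
        rng = rng or np.random.default_rng()
        scale = 1.0 / np.sqrt(in_ch * k * k)
        self.W = Param(rng.uniform(-scale, scale, (out_ch, in_ch, k, k)))
        self.W.clip = binary
        self.binary = binary
        self.k, self.stride, self.pad = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch

    def params(self):
        return [self.W]

    def forward(self, x, train):
        self._x_shape = x.shape
        pad_value = -1.0 if self.binary else 0.0
        cols, oh, ow = im2col(x, self.k, self.stride, self.pad, pad_value)
        self._cols = cols  # (F, B*L)
        Wmat = self.W.data.reshape(self.out_ch, -1)
        self._Wb = _sign(Wmat) if self.binary else Wmat
        out = self._Wb @ cols  # (O, B*L)
        B = x.shape[0]
        self._dims = (B, oh, ow)
        return out.reshape(self.out_ch, B, oh * ow).transpose(1, 0, 2).reshape(B, self.out_ch, oh, ow)

    def backward(self, grad):
        B, oh, ow = self._dims
        g = np.ascontiguousarray(
            grad.reshape(B, self.out_ch, oh * ow).transpose(1, 0, 2)
        ).reshape(self.out_ch, -1)
        self.W.grad += (g @ self._cols.T).reshape(self.W.data.shape)  # STE: dWb -> dW
        dcols = self._Wb.T @ g  # (F, B*L)
        return col2im(dcols, self._x_shape, self.k, self.stride, self.pad)


class BinLinear(Layer):
    """Fully connected layer with optionally binarized weights."""

    def __init__(self, in_f, out_f, binary=True, rng=None):
        rng = rng or np.random.default_rng()
        scale = 1.0 / np.sqrt(in_f)
        self.W = Param(rng.uniform(-scale, scale, (out_f, in_f)))
        self.W.clip = binary
        self.binary = binary
        self.in_f, self.out_f = in_f, out_f

    def params(self):
        return [self.W]

    def forward(self, x, train):
        self._x = x
        self._Wb = _sign(self.W.data) if self.binary else self.W.data
        return x @ self._Wb.T

    def backward(self, grad):
        grad = grad.astype(DTYPE, copy=False)
        self.W.grad += grad.T @ self._x
        return grad @ self._Wb


class BatchNorm(Layer):
    """Batch normalization over the channel axis for 2-D or 4-D inputs."""

    def __init__(self, features, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(features))
        self.beta = Param(np.zeros(features))
        self.running_mean = np.zeros(features, dtype=np.float64)
        self.running_var = np.ones(features, dtype=np.float64)
        self.momentum, self.eps = momentum, eps
        self.features = features

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        axes = (0, 2, 3) if x.ndim == 4 else (0,)
        shape = (1, self.features, 1, 1) if x.ndim == 4 else (1, self.features)
        if train:
            mean = x.mean(axis=axes, dtype=np.float64)
            var = x.var(axis=axes, dtype=np.float64)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        self._xhat = (x - mean.astype(DTYPE).reshape(shape)) * self._inv.reshape(shape)
        self._shape, self._axes = shape, axes
        self._m = x.size // self.features
        return self.gamma.data.reshape(shape) * self._xhat + self.beta.data.reshape(shape)

    def backward(self, grad):
        axes, shape = self._axes, self._shape
        dgamma = (grad * self._xhat).sum(axis=axes)
        self.gamma.grad += dgamma.astype(DTYPE)
        self.beta.grad += grad.sum(axis=axes).astype(DTYPE)
        scale = self.gamma.data * self._inv
        m = self._m
        # dx = scale/m * (m*g - sum(g) - xhat * sum(g*xhat))
        out = grad - (self.beta.grad / m).reshape(shape)
        out -= self._xhat * (dgamma.astype(DTYPE) / m).reshape(shape)
        out *= scale.reshape(shape)
        return out


class SignAct(Layer):
    """Binary activation: sign forward, hard-tanh STE backward."""

    def forward(self, x, train):
        self._pre = x
        return _sign(x)

    def backward(self, grad):
        return grad * (np.abs(self._pre) <= 1.0)


class MaxPool2d(Layer):
    """Non-overlapping max pooling (kernel == stride, dims must divide)."""

    def __init__(self, k):
        self.k = k

    def forward(self, x, train):
        B, C, H, W = x.shape
        k = self.k
        if H % k or W % k:
            raise ValueError(f"pooling kernel {k} must divide spatial dims {(H, W)}")
        xr = x.reshape(B, C, H // k, k, W // k, k)
        out = xr.max(axis=(3, 5))
        # break ties: route the gradient to the first max per window only
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // k, W // k, k * k)
        first = np.argmax(flat, axis=-1)
        sel = np.zeros_like(flat)
        np.put_along_axis(sel, first[..., None], 1, axis=-1)
        self._mask = sel.reshape(B, C, H // k, W // k, k, k).transpose(0, 1, 2, 4, 3, 5)
        self._x_shape = x.shape
        return out

    def backward(self, grad):
        B, C, H, W = self._x_shape
        k = self.k
        g = grad[:, :, :, None, :, None] * self._mask
        return g.reshape(B, C, H, W)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class PresentationAggregate(Layer):
    """Aggregate per-presentation sign maps: (B*N, ...) -> (B, ...).

    Forward is sign of the presentation mean (== sign of the sum, ties to
    +1); backward distributes the STE gradient uniformly over the N
    presentations.
    """

    def __init__(self, n_pre: int):
        self.n_pre = n_pre

    def forward(self, x, train):
        n = self.n_pre
        B = x.shape[0] // n
        self._mean = x.reshape(B, n, *x.shape[1:]).mean(axis=1)
        return _sign(self._mean)

    def backward(self, grad):
        g = grad * (np.abs(self._mean) <= 1.0) / DTYPE(self.n_pre)
        out = np.broadcast_to(g[:, None], (g.shape[0], self.n_pre) + g.shape[1:])
        return out.reshape(-1, *grad.shape[1:])


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax_xent(scores: np.ndarray, labels: np.ndarray, scale: float = 1.0):
    """Mean softmax cross-entropy on ``scale * scores``; returns (loss, dscores)."""
    z = scale * scores.astype(np.float64)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    B = scores.shape[0]
    loss = -np.log(p[np.arange(B), labels] + 1e-300).mean()
    dp = p.copy()
    dp[np.arange(B), labels] -= 1.0
    return float(loss), (scale * dp / B).astype(DTYPE)


class Adam:
    """Adam with post-update clipping of binarized shadow weights."""

    def __init__(self, params: list[Param], lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
            if p.clip:
                np.clip(p.data, -1.0, 1.0, out=p.data)
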