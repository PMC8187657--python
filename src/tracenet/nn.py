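"""Minimal dense/convolutional network engine with manual backprop.

Implements exactly the pieces the classifiers in this package need:
2D convolution (same padding, stride 1), batch normalization, ReLU, 2x2 max
pooling, dense layers, a numerically stable binary cross-entropy on logits,
and the AdamW optimizer (decoupled weight decay). Everything is plain
numpy; gradients flow all the way back to the input, which is what the
expected-gradients attribution in :mod:`tracenet.interpret` consumes.

Correctness of every backward pass is pinned by finite-difference gradient
checks in the test suite.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A weight array with its gradient buffer and a weight-decay flag."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


# ---------------------------------------------------------------------------
# im2col helpers (stride-1, same padding)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix."""
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (N, C, k, k, H, W), (s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return np.ascontiguousarray(win).reshape(N, C * k * k, H * W)


def _col2im(cols: np.ndarray, xshape, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    N, C, H, W = xshape
    cols = cols.reshape(N, C, k, k, H, W)
    xp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + H, j : j + W] += cols[:, :, i, j]
    return xp[:, :, pad : pad + H, pad : pad + W]


class Conv2d(Layer):
    """Stride-1 'same' convolution, He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng, dtype=np.float32):
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel))
        self.w = Parameter(w.astype(dtype), decay=True)
        self.b = Parameter(np.zeros(out_ch, dtype=dtype), decay=False)
        self.kernel = kernel
        self.pad = kernel // 2

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        N, C, H, W = x.shape
        self._xshape = x.shape
        self._cols = _im2col(x, self.kernel, self.pad)  # (N, Ckk, HW)
        F = self.w.value.shape[0]
        wmat = self.w.value.reshape(F, -1)
        out = np.matmul(wmat, self._cols)  # batched GEMM -> (N, F, HW)
        out += self.b.value[None, :, None]
        return out.reshape(N, F, H, W)

    def backward(self, dout):
        N, F, H, W = dout.shape
        dflat = dout.reshape(N, F, H * W)
        self.w.grad[...] = np.matmul(
            dflat, self._cols.transpose(0, 2, 1)
        ).sum(axis=0).reshape(self.w.value.shape)
        self.b.grad[...] = dflat.sum(axis=(0, 2))
        wT = np.ascontiguousarray(self.w.value.reshape(F, -1).T)
        dcols = np.matmul(wT, dflat)
        return _col2im(dcols, self._xshape, self.kernel, self.pad)


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Parameter(np.ones(ch, dtype=dtype), decay=False)
        self.beta = Parameter(np.zeros(ch, dtype=dtype), decay=False)
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        axes = (0, 2, 3)
        self._train = train
        if train:
            mean = x.mean(axis=axes)
            var = (x * x).mean(axis=axes) - mean * mean
            np.maximum(var, 0.0, out=var)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(x.dtype)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        istd = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        self._x, self._mean, self._istd = x, mean.astype(x.dtype), istd
        # single fused scale-shift pass: out = x*A + B
        A = (self.gamma.value * istd).astype(x.dtype)
        B = (self.beta.value - self.gamma.value * mean * istd).astype(x.dtype)
        out = x * A[None, :, None, None]
        out += B[None, :, None, None]
        return out

    def _xhat(self):
        xh = self._x - self._mean[None, :, None, None]
        xh *= self._istd[None, :, None, None]
        return xh

    def backward(self, dout):
        g = self.gamma.value[None, :, None, None]
        istd = self._istd[None, :, None, None]
        xhat = self._xhat()
        self.gamma.grad[...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad[...] = dout.sum(axis=(0, 2, 3))
        if not self._train:
            return dout * (g * istd)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dxhat = dout * g
        dx = m * dxhat
        dx -= dxhat.sum(axis=(0, 2, 3), keepdims=True)
        dx -= xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx *= istd / m
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2 (trailing odd row/column cropped).

    The backward pass routes gradient to every element equal to the window
    maximum; exact ties occur only at ReLU zeros, whose gradient the
    preceding ReLU mask kills anyway.
    """

    def forward(self, x, train):
        N, C, H, W = x.shape
        Ho, Wo = H // 2, W // 2
        self._x = x
        rows = np.maximum(x[:, :, 0 : Ho * 2 : 2, : Wo * 2], x[:, :, 1 : Ho * 2 : 2, : Wo * 2])
        out = np.maximum(rows[:, :, :, 0::2], rows[:, :, :, 1::2])
        self._out = out
        return out

    def backward(self, dout):
        x = self._x
        N, C, H, W = x.shape
        Ho, Wo = dout.shape[2], dout.shape[3]
        dx = np.zeros((N, C, H, W), dtype=dout.dtype)
        for di in (0, 1):
            for dj in (0, 1):
                sub = x[:, :, di : Ho * 2 : 2, dj : Wo * 2 : 2]
                dx[:, :, di : Ho * 2 : 2, dj : Wo * 2 : 2] = np.where(
                    sub == self._out, dout, 0
                )
        return dx


class AvgBlur2d(Layer):
    """Fixed k x k mean filter, stride 1, same padding (no parameters).

    A non-learned smoothing front end: each matrix entry is replaced by its
    neighborhood mean, hardwiring the prior that adjacent barcodes carry
    redundant information. Self-adjoint, so backward applies the same blur.
    """

    def __init__(self, k: int = 5):
        if k % 2 != 1:
            raise ValueError("blur kernel must be odd")
        self.k = k

    def _blur(self, x):
        k, pad = self.k, self.k // 2
        N, C, H, W = x.shape
        out = np.zeros_like(x)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        for i in range(k):
            for j in range(k):
                out += xp[:, :, i : i + H, j : j + W]
        out /= k * k
        return out

    def forward(self, x, train):
        return self._blur(x)

    def backward(self, dout):
        return self._blur(dout)


class AvgPool2d(Layer):
    """k x k average pooling, stride k (input cropped to a multiple of k)."""

    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x, train):
        k = self.k
        N, C, H, W = x.shape
        Ho, Wo = H // k, W // k
        self._xshape = x.shape
        return (
            x[:, :, : Ho * k, : Wo * k]
            .reshape(N, C, Ho, k, Wo, k)
            .mean(axis=(3, 5))
        )

    def backward(self, dout):
        k = self.k
        N, C, H, W = self._xshape
        Ho, Wo = dout.shape[2], dout.shape[3]
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        dx[:, :, : Ho * k, : Wo * k] = (
            dout.repeat(k, axis=2).repeat(k, axis=3) / (k * k)
        )
        return dx


class CoordChannels(Layer):
    """Append constant row/col coordinate maps (CoordConv-style).

    Gives weight-shared convolutional detectors access to absolute genomic
    position, so a contact detector can remain specific to one locus pair
    even under a global-average-pooled head. Input (N,1,H,W) -> (N,3,H,W).
    """

    def forward(self, x, train):
        N, C, H, W = x.shape
        r = np.linspace(-1.0, 1.0, H, dtype=x.dtype)
        c = np.linspace(-1.0, 1.0, W, dtype=x.dtype)
        rows = np.broadcast_to(r[None, None, :, None], (N, 1, H, W))
        cols = np.broadcast_to(c[None, None, None, :], (N, 1, H, W))
        return np.concatenate([x, rows, cols], axis=1)

    def backward(self, dout):
        return dout[:, :1]


class GlobalAvgPool(Layer):
    """Spatial mean over each feature map: (N,C,H,W) -> (N,C)."""

    def forward(self, x, train):
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        N, C, H, W = self._xshape
        return np.broadcast_to(
            dout[:, :, None, None] / (H * W), self._xshape
        ).astype(dout.dtype).copy()


class Flatten(Layer):
    def forward(self, x, train):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng, dtype=np.float32,
                 bias_init: float = 0.0):
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.w = Parameter(w.astype(dtype), decay=True)
        self.b = Parameter(np.full(n_out, bias_init, dtype=dtype), decay=False)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad[...] = self._x.T @ dout
        self.b.grad[...] = dout.sum(axis=0)
        return dout @ self.w.value.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Propagate to every parameter gradient and return d(loss)/d(input)."""
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """Gradient of the summed output logit w.r.t. the input (eval mode)."""
        out = self.forward(x, train=False)
        return self.backward(np.ones_like(out))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    z = logits.reshape(-1)
    y = y.reshape(-1).astype(z.dtype)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = (sigmoid(z) - y) / len(z)
    return float(loss), dz.reshape(logits.shape).astype(logits.dtype)


class AdamW:
    """Adam with decoupled weight decay (applied only to decay-flagged params)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        weight_decay: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if p.decay and self.weight_decay:
                update = update + self.weight_decay * p.value
            p.value -= (self.lr * update).astype(p.value.dtype)
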