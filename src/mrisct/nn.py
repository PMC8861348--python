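"""Minimal CPU neural-network primitives with manual backpropagation.

Just enough machinery for a paired image-to-image conditional GAN at
desk scale: 2D convolution and transpose convolution (im2col based),
batch normalization, dropout, the usual activations, a fully connected
layer and an Adam optimizer.  All randomness flows through explicitly
passed numpy Generators, so training runs are reproducible bit-for-bit
for a fixed seed.

Array layout is (N, C, H, W) throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Unfold k x k patches: (N, C, H, W) -> (N, C*k*k, Ho*Wo)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = as_strided(
        x, (n, c, k, k, ho, wo), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    return np.ascontiguousarray(cols).reshape(n, c * k * k, ho * wo)


def col2im(gcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patch gradients back."""
    n, c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    g = gcols.reshape(n, c, k, k, ho, wo)
    gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for i in range(k):
        for j in range(k):
            gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += g[
                :, :, i, j
            ]
    if pad:
        gx = gx[:, :, pad : pad + h, pad : pad + w]
    return gx


class Layer:
    """Base layer; parameters and their gradients are parallel lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, cin, cout, k=3, stride=1, pad=None, init_sd=1e-4, rng=None):
        super().__init__()
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, init_sd, size=(cout, cin, k, k))
        self.b = np.zeros(cout)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        self._x_shape = x.shape
        self._cols = im2col(x, self.k, self.stride, self.pad)
        n = x.shape[0]
        cout = self.W.shape[0]
        wf = self.W.reshape(cout, -1)
        out = wf @ self._cols + self.b[None, :, None]
        h = (x.shape[2] + 2 * self.pad - self.k) // self.stride + 1
        w = (x.shape[3] + 2 * self.pad - self.k) // self.stride + 1
        return out.reshape(n, cout, h, w)

    def backward(self, g):
        n, cout = g.shape[:2]
        gf = g.reshape(n, cout, -1)
        self.grads[0][...] = np.einsum("ncl,nkl->ck", gf, self._cols).reshape(self.W.shape)
        self.grads[1][...] = gf.sum(axis=(0, 2))
        wf = self.W.reshape(cout, -1)
        gcols = np.einsum("ck,ncl->nkl", wf, gf)
        return col2im(gcols, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2D(Layer):
    """3x3 stride-2 transpose convolution doubling the spatial size."""

    def __init__(self, cin, cout, k=3, stride=2, init_sd=1e-4, rng=None):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, (k - 1) // 2
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, init_sd, size=(cin, cout, k, k))
        self.b = np.zeros(cout)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        n, cin, h, w = x.shape
        self._x = x
        cout = self.W.shape[1]
        self._out_shape = (n, cout, h * self.stride, w * self.stride)
        wf = self.W.reshape(cin, -1)  # (cin, cout*k*k)
        gcols = np.einsum("ck,ncl->nkl", wf, x.reshape(n, cin, -1))
        out = col2im(gcols, self._out_shape, self.k, self.stride, self.pad)
        return out + self.b[None, :, None, None]

    def backward(self, g):
        n, cin = self._x.shape[:2]
        cols = im2col(g, self.k, self.stride, self.pad)  # (n, cout*k*k, h*w)
        xf = self._x.reshape(n, cin, -1)
        self.grads[0][...] = np.einsum("ncl,nkl->ck", xf, cols).reshape(self.W.shape)
        self.grads[1][...] = g.sum(axis=(0, 2, 3))
        wf = self.W.reshape(cin, -1)
        gx = np.einsum("ck,nkl->ncl", wf, cols)
        return gx.reshape(self._x.shape)


class BatchNorm2D(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        self._train = train
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, g):
        self.grads[0][...] = (g * self._xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = g.sum(axis=(0, 2, 3))
        gxhat = g * self.gamma[None, :, None, None]
        if not self._train:
            return gxhat / self._std
        m = g.shape[0] * g.shape[2] * g.shape[3]
        return (
            gxhat - gxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (gxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        ) / self._std


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g):
        return np.where(self._mask, g, self.slope * g)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, g):
        return g * (1 - self._y**2)


class Dropout(Layer):
    def __init__(self, rate=0.5, rng=None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=True):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Linear(Layer):
    def __init__(self, fin, fout, init_sd=1e-4, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, init_sd, size=(fout, fin))
        self.b = np.zeros(fout)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, g):
        self.grads[0][...] = g.T @ self._x
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    @property
    def all_params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def all_grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class Adam:
    def __init__(self, params, grads, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def bce_with_logits(z: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dL/dz)."""
    # softplus(z) - t*z, numerically stable
    loss = float(np.mean(np.logaddexp(0.0, z) - target * z))
    grad = (sigmoid(z) - target) / z.size
    return loss, grad


def l1_loss(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error; returns (loss, dL/da)."""
    diff = a - b
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size
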