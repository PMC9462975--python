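"""Minimal NumPy building blocks for small 3D convolutional networks.

Each layer implements ``forward(x)`` / ``backward(dy)`` with an internal
cache, single-sample (no batch axis) semantics and float32 arithmetic.
Tensors are ``(C, H, W, S)``. Convolutions are lowered to GEMM via
im2col, which is where essentially all the runtime goes; everything is
deterministic given the seeds fed to the initializers.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A learnable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    @property
    def size(self) -> int:
        return self.value.size


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / max(fan_in, 1))).astype(DTYPE)


# ---------------------------------------------------------------------------
# im2col machinery for 3x3x3 same-padding convolutions

def _im2col(x: np.ndarray, k: int, pad: int, out: np.ndarray | None = None) -> np.ndarray:
    """(C, D, H, W) -> (C*k^3, D*H*W) patch matrix via k^3 slice copies."""
    c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    n = d * h * w
    if out is None or out.shape != (c, k * k * k, n):
        out = np.empty((c, k * k * k, n), dtype=x.dtype)
    ov = out.reshape(c, k * k * k, d, h, w)
    i = 0
    for a in range(k):
        for b in range(k):
            for cc in range(k):
                ov[:, i] = xp[:, a:a + d, b:b + h, cc:cc + w]
                i += 1
    return out


def _col2im(colg: np.ndarray, shape, k: int, pad: int, buf: np.ndarray | None = None) -> np.ndarray:
    """Scatter-add the patch-matrix gradient back onto the input grid."""
    c, d, h, w = shape
    pshape = (c, d + 2 * pad, h + 2 * pad, w + 2 * pad)
    if buf is None or buf.shape != pshape:
        buf = np.zeros(pshape, dtype=colg.dtype)
    else:
        buf[...] = 0.0
    colg = colg.reshape(c, k, k, k, d, h, w)
    for a in range(k):
        for b in range(k):
            for cc in range(k):
                buf[:, a:a + d, b:b + h, cc:cc + w] += colg[:, a, b, cc]
    return buf[:, pad:pad + d, pad:pad + h, pad:pad + w]


class Conv3d(object):
    """3x3x3 (or 1x1x1) convolution with 'same' padding, stride 1."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, kernel: int = 3):
        self.cin, self.cout, self.k = cin, cout, kernel
        self.pad = kernel // 2
        fan_in = cin * kernel ** 3
        self.weight = Param(he_normal(rng, (cout, cin, kernel, kernel, kernel), fan_in))
        self.bias = Param(np.zeros(cout, dtype=DTYPE))
        self._cache = None
        # buffers reused across steps; spatial size is fixed per layer
        self._colbuf = None
        self._colgbuf = None
        self._padbuf = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if self.k == 1:
            y = np.tensordot(self.weight.value[:, :, 0, 0, 0], x, axes=([1], [0]))
            y += self.bias.value[:, None, None, None]
            self._cache = (x, None)
            return y
        self._colbuf = _im2col(x, self.k, self.pad, self._colbuf)
        col = self._colbuf.reshape(self.cin * self.k ** 3, -1)
        w2 = self.weight.value.reshape(self.cout, -1)
        y = (w2 @ col) + self.bias.value[:, None]
        self._cache = (x, col)
        return y.reshape(self.cout, d, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, col = self._cache
        c, d, h, w = x.shape
        dy2 = dy.reshape(self.cout, -1)
        self.bias.grad += dy2.sum(axis=1)
        if self.k == 1:
            self.weight.grad[:, :, 0, 0, 0] += dy2 @ x.reshape(c, -1).T
            return np.tensordot(self.weight.value[:, :, 0, 0, 0].T, dy, axes=([1], [0]))
        self.weight.grad += (dy2 @ col.T).reshape(self.weight.value.shape)
        w2 = np.ascontiguousarray(self.weight.value.reshape(self.cout, -1).T)
        if self._colgbuf is None or self._colgbuf.shape != (w2.shape[0], dy2.shape[1]):
            self._colgbuf = np.empty((w2.shape[0], dy2.shape[1]), dtype=dy2.dtype)
        np.matmul(w2, dy2, out=self._colgbuf)
        pshape = (c, d + 2 * self.pad, h + 2 * self.pad, w + 2 * self.pad)
        if self._padbuf is None or self._padbuf.shape != pshape:
            self._padbuf = np.zeros(pshape, dtype=dy2.dtype)
        return _col2im(self._colgbuf, x.shape, self.k, self.pad, self._padbuf)


class ReLU(object):
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2(object):
    """2x2x2 max pooling with stride 2; requires even spatial dims."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        r = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        r = r.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        idx = r.argmax(axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (c, d, h, w), idx = self._cache
        dr = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
        np.put_along_axis(dr, idx[..., None], dy[..., None], axis=-1)
        dr = dr.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        return dr.reshape(c, d, h, w)


class ConvTranspose2(object):
    """2x2x2 transposed convolution with stride 2 (learned upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        self.weight = Param(he_normal(rng, (cin, cout, 2, 2, 2), cin))
        self.bias = Param(np.zeros(cout, dtype=DTYPE))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        y = np.einsum("idhw,ioabc->odahbwc", x, self.weight.value, optimize=True)
        y = y.reshape(self.cout, 2 * d, 2 * h, 2 * w) + self.bias.value[:, None, None, None]
        self._cache = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        c, d, h, w = x.shape
        dyr = dy.reshape(self.cout, d, 2, h, 2, w, 2)
        self.bias.grad += dy.sum(axis=(1, 2, 3))
        self.weight.grad += np.einsum("odahbwc,idhw->ioabc", dyr, x, optimize=True)
        return np.einsum("odahbwc,ioabc->idhw", dyr, self.weight.value, optimize=True)


class Linear(object):
    """Dense map on channel vectors (used inside the attention block)."""

    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.weight = Param(he_normal(rng, (nout, nin), nin))
        self.bias = Param(np.zeros(nout, dtype=DTYPE))
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return self.weight.value @ x + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += np.outer(dy, self._x)
        self.bias.grad += dy
        return self.weight.value.T @ dy


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Softmax over axis 0 of a (C, ...) array, numerically stabilized."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


class Adam(object):
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(p.grad)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
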