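"""Minimal NumPy neural-network engine: layers with manual backprop.

Implements exactly the pieces the dilated-ResNet feature extractor needs:
2-D (dilated) convolution via im2col, batch normalization, ReLU, linear
layers, bilinear upsampling, global average pooling, softmax cross-entropy
and Adam.  Every layer keeps a stack of forward caches, so a layer object
may be applied several times in one forward pass (e.g. weight sharing
across attention branches) provided backward calls unwind in reverse
order.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base class: parameters, persistent buffers, and a cache stack."""

    def __init__(self) -> None:
        self._cache: list = []

    def params(self) -> list[tuple[str, Param]]:
        return []

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def clear_caches(self) -> None:
        """Drop forward caches (inference-only passes never pop them)."""
        self._cache.clear()

    __call__ = forward


# ---------------------------------------------------------------------------
# dilated convolution
# ---------------------------------------------------------------------------

def _same_padding(kernel: int, dilation: int) -> int:
    if kernel % 2 == 0:
        raise ValueError("'same' padding requires an odd kernel size")
    return dilation * (kernel - 1) // 2


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dil: int,
            out_h: int, out_w: int) -> np.ndarray:
    n, c, _, _ = xp.shape
    s0, s1, s2, s3 = xp.strides
    view = as_strided(
        xp,
        shape=(n, c, kh, kw, out_h, out_w),
        strides=(s0, s1, s2 * dil, s3 * dil, s2 * stride, s3 * stride),
    )
    return np.ascontiguousarray(view).reshape(n, c * kh * kw, out_h * out_w)


def conv2d_forward(
    x: np.ndarray,
    weight: np.ndarray,
    bias: np.ndarray | None = None,
    stride: int = 1,
    dilation: int = 1,
    padding: str = "same",
) -> tuple[np.ndarray, tuple]:
    """Batched cross-correlation with dilation.

    ``x`` is ``N x C_in x H x W``; ``weight`` is ``C_out x C_in x K_h x K_w``.
    With dilation rate r, output position (u, v) sums
    ``x[u*stride + k*r, v*stride + l*r] * weight[k, l]`` over the kernel
    index set, i.e. kernel taps are spaced r pixels apart.
    """
    n, c_in, h, w = x.shape
    c_out, c_in_w, kh, kw = weight.shape
    if c_in != c_in_w:
        raise ValueError(f"input has {c_in} channels, kernel expects {c_in_w}")
    if dilation < 1 or stride < 1:
        raise ValueError("stride and dilation must be >= 1")
    if padding == "same":
        ph, pw = _same_padding(kh, dilation), _same_padding(kw, dilation)
    elif padding == "valid":
        ph = pw = 0
    else:
        raise ValueError(f"unknown padding {padding!r}")
    eff_h, eff_w = dilation * (kh - 1) + 1, dilation * (kw - 1) + 1
    out_h = (h + 2 * ph - eff_h) // stride + 1
    out_w = (w + 2 * pw - eff_w) // stride + 1
    if out_h < 1 or out_w < 1:
        raise ValueError("kernel does not fit the padded input")
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = _im2col(xp, kh, kw, stride, dilation, out_h, out_w)
    w2 = weight.reshape(c_out, -1)
    y = np.matmul(w2, cols)  # (N, C_out, L)
    if bias is not None:
        y += bias[None, :, None]
    y = y.reshape(n, c_out, out_h, out_w)
    cache = (cols, weight.shape, xp.shape, (ph, pw), stride, dilation, w2)
    return y, cache


def conv2d_backward(
    dy: np.ndarray, cache: tuple
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dweight, dbias) of :func:`conv2d_forward`."""
    cols, wshape, xpshape, (ph, pw), stride, dil, w2 = cache
    c_out, c_in, kh, kw = wshape
    n, _, out_h, out_w = dy.shape
    dyf = dy.reshape(n, c_out, out_h * out_w)
    dw = np.einsum("nol,nkl->ok", dyf, cols).reshape(wshape)
    db = dy.sum(axis=(0, 2, 3))
    dcols = np.matmul(w2.T, dyf).reshape(n, c_in, kh, kw, out_h, out_w)
    dxp = np.zeros(xpshape, dtype=dy.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i * dil: i * dil + out_h * stride: stride,
                j * dil: j * dil + out_w * stride: stride] += dcols[:, :, i, j]
    h = xpshape[2] - 2 * ph
    w = xpshape[3] - 2 * pw
    dx = dxp[:, :, ph: ph + h, pw: pw + w]
    return dx, dw, db


def dilated_conv2d(
    image: np.ndarray,
    kernel: np.ndarray,
    rate: int,
    padding: str = "same",
) -> np.ndarray:
    """Dilated cross-correlation of one ``C x H x W`` feature map.

    ``kernel`` is ``C_out x C_in x K_h x K_w``; the result has the same
    spatial size as the input under ``"same"`` zero padding.
    """
    x = np.asarray(image, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError(f"expected C x H x W input, got shape {x.shape}")
    y, _ = conv2d_forward(x[None], np.asarray(kernel, dtype=np.float64),
                          stride=1, dilation=rate, padding=padding)
    return y[0]


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 dilation: int = 1, padding: str = "same",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        self.weight = Param(w)
        self.bias = Param(np.zeros(c_out))
        self.stride, self.dilation, self.padding = stride, dilation, padding
        if padding == "same" and kernel % 2 == 0:
            raise ValueError("'same' padding requires an odd kernel size")

    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x, train=False):
        y, cache = conv2d_forward(x, self.weight.value, self.bias.value,
                                  self.stride, self.dilation, self.padding)
        self._cache.append(cache)
        return y

    def backward(self, dy):
        dx, dw, db = conv2d_backward(dy, self._cache.pop())
        self.weight.grad += dw
        self.bias.grad += db
        return dx


# ---------------------------------------------------------------------------
# normalization / activations / pooling
# ---------------------------------------------------------------------------

class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def buffers(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_sd[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        self._cache.append((xhat, inv_sd, train, x.shape))
        return y

    def backward(self, dy):
        xhat, inv_sd, train, shape = self._cache.pop()
        n_eff = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv_sd[None, :, None, None]
        if not train:
            return dy * g
        dxhat = dy * self.gamma.value[None, :, None, None]
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) \
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / n_eff
        return term * inv_sd[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=False):
        mask = x > 0
        self._cache.append(mask)
        return x * mask

    def backward(self, dy):
        return dy * self._cache.pop()


class GlobalAvgPool2d(Layer):
    """N x C x H x W -> N x C spatial mean."""

    def forward(self, x, train=False):
        self._cache.append(x.shape)
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._cache.pop()
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in)))
        self.bias = Param(np.zeros(d_out))

    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x, train=False):
        self._cache.append(x)
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy):
        x = self._cache.pop()
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic interpolation matrix (half-pixel centers, edge clamp)."""
    a = np.zeros((n_out, n_in))
    for o in range(n_out):
        src = (o + 0.5) * n_in / n_out - 0.5
        i0 = int(np.floor(src))
        t = src - i0
        j0 = min(max(i0, 0), n_in - 1)
        j1 = min(max(i0 + 1, 0), n_in - 1)
        a[o, j0] += 1.0 - t
        a[o, j1] += t
    return a


class BilinearUpsample(Layer):
    """Resize N x C x H x W maps to a fixed spatial size."""

    def __init__(self, out_size: tuple[int, int]):
        super().__init__()
        self.out_size = out_size
        self._mats: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def forward(self, x, train=False):
        h, w = x.shape[2], x.shape[3]
        key = (h, w)
        if key not in self._mats:
            self._mats[key] = (
                _bilinear_matrix(self.out_size[0], h).astype(x.dtype),
                _bilinear_matrix(self.out_size[1], w).astype(x.dtype),
            )
        ah, aw = self._mats[key]
        self._cache.append(key)
        return np.einsum("oh,nchw,pw->ncop", ah, x, aw, optimize=True)

    def backward(self, dy):
        ah, aw = self._mats[self._cache.pop()]
        return np.einsum("oh,ncop,pw->nchw", ah, dy, aw, optimize=True)


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Adam:
    def __init__(self, params: list[Param], lr: float = 0.002,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad * p.grad - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
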