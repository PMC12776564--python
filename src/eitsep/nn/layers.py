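"""Minimal CNN layer zoo on numpy (float32) with explicit backprop.

Everything is sized for small segmentation networks on 32x32 grids: 3x3
same-padding convolutions via im2col + one large GEMM, 2x2 max pooling,
nearest-neighbour 2x upsampling, ReLU, channel concatenation.  Each layer
caches what its backward pass needs; gradients accumulate on the layer's
parameters so a shared submodule (the U-Net encoder) can receive gradient
contributions from several downstream paths before the optimizer step.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (C*9, N*H*W) patch matrix for 3x3 same convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((c, 9, n, h, w), dtype=DTYPE)
    for ki in range(3):
        for kj in range(3):
            cols[:, ki * 3 + kj] = xp[:, :, ki:ki + h, kj:kj + w].transpose(1, 0, 2, 3)
    return cols.reshape(c * 9, n * h * w)


def _col2im3(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col3`."""
    n, c, h, w = shape
    d = dcols.reshape(c, 9, n, h, w)
    out = np.zeros((n, c, h + 2, w + 2), dtype=DTYPE)
    for ki in range(3):
        for kj in range(3):
            out[:, :, ki:ki + h, kj:kj + w] += d[:, ki * 3 + kj].transpose(1, 0, 2, 3)
    return out[:, :, 1:-1, 1:-1]


class Conv3x3:
    """3x3 convolution, stride 1, same padding, He fan-in init.

    Uses the numba direct-convolution backend when available
    (``backend="numba"``, the default there); ``backend="numpy"`` selects
    the im2col + GEMM reference path.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 backend: str | None = None) -> None:
        std = np.sqrt(2.0 / (c_in * 9))
        self.w = Parameter(rng.normal(0.0, std, (c_out, c_in * 9)))
        self.b = Parameter(np.zeros(c_out))
        if backend is None:
            # both backends run at comparable speed at these sizes; the
            # numpy path avoids JIT warmup and is the default
            backend = "numpy"
        if backend not in ("numba", "numpy"):
            raise ValueError(f"unknown conv backend {backend!r}")
        self.backend = backend
        self._cols: np.ndarray | None = None
        self._x: np.ndarray | None = None
        self._xshape: tuple[int, int, int, int] | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    @property
    def _w4(self) -> np.ndarray:
        co, c9 = self.w.value.shape
        return np.ascontiguousarray(
            self.w.value.reshape(co, c9 // 9, 3, 3))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.backend == "numba":
            from .fastconv import conv3x3_forward, pad_input
            self._x = pad_input(x)
            return conv3x3_forward(self._x, self._w4,
                                   self.b.value.astype(DTYPE))
        n, c, h, w = x.shape
        self._xshape = x.shape
        self._cols = _im2col3(x.astype(DTYPE, copy=False))
        y = self.w.value @ self._cols + self.b.value[:, None]
        return y.reshape(-1, n, h, w).transpose(1, 0, 2, 3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.backend == "numba":
            from .fastconv import conv3x3_backward
            dx, dw, db = conv3x3_backward(
                self._x, self._w4, np.ascontiguousarray(dy, dtype=DTYPE))
            dx = np.ascontiguousarray(dx)
            self.w.grad += dw.reshape(self.w.value.shape)
            self.b.grad += db
            return dx
        n, co, h, w = dy.shape
        dyf = dy.transpose(1, 0, 2, 3).reshape(co, n * h * w)
        self.w.grad += dyf @ self._cols.T
        self.b.grad += dyf.sum(axis=1)
        dcols = self.w.value.T @ dyf
        return _col2im3(dcols, self._xshape)


class Conv1x1:
    """1x1 convolution (per-pixel linear map), used for the output heads."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        std = np.sqrt(2.0 / c_in)
        self.w = Parameter(rng.normal(0.0, std, (c_out, c_in)))
        self.b = Parameter(np.zeros(c_out))
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("oc,nchw->nohw", self.w.value, x,
                         optimize=True) + self.b.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += np.einsum("nohw,nchw->oc", dy, self._x, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return np.einsum("oc,nohw->nchw", self.w.value, dy, optimize=True)


class LeakyReLU:
    """Rectifier with a small negative-side slope.

    The leak (default 0.01) keeps gradient flowing through units that an
    early optimizer step pushed negative; with a plain ReLU an entire
    task decoder can die under Adam when its loss weight is small.
    """

    def __init__(self, slope: float = 0.01) -> None:
        self.slope = slope
        self._mask: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, DTYPE(self.slope) * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, DTYPE(self.slope) * dy)


ReLU = LeakyReLU  # nonlinearity used throughout the U-Net blocks


class MaxPool2x2:
    def __init__(self) -> None:
        self._idx: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = (x.reshape(n, c, h // 2, 2, w // 2, 2)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, c, h // 2, w // 2, 4))
        # first argmax only: tied window values (e.g. ReLU zeros) must not
        # receive duplicated gradient
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], -1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dy.shape
        d = np.zeros((n, c, h2, w2, 4), dtype=dy.dtype)
        np.put_along_axis(d, self._idx[..., None], dy[..., None], -1)
        return (d.reshape(n, c, h2, w2, 2, 2)
                 .transpose(0, 1, 2, 4, 3, 5)
                 .reshape(n, c, h2 * 2, w2 * 2))


class Upsample2x:
    """Nearest-neighbour 2x upsampling."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class BatchNorm2d:
    """Per-channel batch normalization with learnable scale and shift.

    Normalizes over (batch, height, width) with batch statistics during
    training and exponential running averages at inference.  Essential
    here: the heart-related contrast occupies only a few percent of the
    input dynamic range, and per-channel renormalization lets early
    layers amplify it without fighting the lung-dominated scale.
    """

    def __init__(self, c: int, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(x.dtype)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        self._xhat = ((x - mean[None, :, None, None])
                      * inv[None, :, None, None])
        self._inv = inv
        return (self.gamma.value[None, :, None, None] * self._xhat
                + self.beta.value[None, :, None, None])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gamma.grad += (dy * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not self.training:
            return dy * g * self._inv[None, :, None, None]
        n, _, h, w = dy.shape
        m = n * h * w
        dxhat = dy * g
        # standard batch-norm gradient through the batch statistics
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * self._xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (self._inv[None, :, None, None] / m
                * (m * dxhat - s1 - self._xhat * s2)).astype(dy.dtype)


class ConvBlock:
    """(Conv3x3 -> BatchNorm -> ReLU) x 2, one U-Net level block."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        self.layers = [Conv3x3(c_in, c_out, rng), BatchNorm2d(c_out), ReLU(),
                       Conv3x3(c_out, c_out, rng), BatchNorm2d(c_out), ReLU()]

    def parameters(self) -> list[Parameter]:
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    """Adam with bias correction; one optimizer owns all model parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def stable_sigmoid(x) -> np.ndarray:
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
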