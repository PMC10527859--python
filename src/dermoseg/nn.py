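"""Minimal numpy convolutional-network core.

Implements exactly the layer set the ResNet-UNet needs — 2-D convolution,
batch normalization, ReLU/sigmoid, 3x3 max-pooling, nearest-neighbour x2
up-sampling — each as a small object with explicit ``forward``/``backward``
methods, plus an Adam optimizer.  Convolutions are evaluated by an
im2col/GEMM lowering so the heavy arithmetic runs inside BLAS; backward
passes are hand-derived and are validated against finite differences in the
test suite.

Tensors are NCHW float64 by default (float32 during training for speed);
all shapes are static once a layer is constructed.  This core intentionally
implements no autograd graph: the network classes wire their own backward
passes, which keeps every gradient path explicit and testable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "UpsampleNearest2d",
    "Adam",
    "he_normal",
]


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """He/Kaiming normal initialisation suited to ReLU networks."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Param:
    """A weight tensor with its gradient accumulator and a trainable flag."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, name: str = "", trainable: bool = True):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


class Module:
    """Base class: children discovered by attribute scan, depth-first."""

    def parameters(self) -> list[Param]:
        out: list[Param] = []

        def collect(obj):
            if isinstance(obj, Param):
                out.append(obj)
            elif isinstance(obj, Module):
                out.extend(obj.parameters())
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    collect(item)

        for attr in vars(self).values():
            collect(attr)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def set_trainable(self, flag: bool) -> None:
        for p in self.parameters():
            p.trainable = flag


# ---------------------------------------------------------------------------
# im2col / col2im lowering


def _im2col(x: np.ndarray, k: int, stride: int, pad: int, pad_value: float = 0.0):
    n, c, h, w = x.shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    if pad:
        xp = np.full((n, c, h + 2 * pad, w + 2 * pad), pad_value, dtype=x.dtype)
        xp[:, :, pad : pad + h, pad : pad + w] = x
    else:
        xp = x
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow), (oh, ow)


def _col2im(dcols: np.ndarray, xshape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = xshape
    l = dcols.shape[-1]
    # recover spatial extents from the forward geometry
    oh = (h + 2 * pad - k) // stride + 1
    ow = l // oh
    d6 = dcols.reshape(n, c, k, k, oh, ow)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d6[:, :, i, j]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Conv2d(Module):
    """k x k convolution, optional bias (omitted where batch-norm follows)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int | None = None,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Param(
            he_normal(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in),
            name=f"{name}.weight",
        )
        self.bias = Param(np.zeros(out_channels), name=f"{name}.bias") if bias else None
        self._cache = None

    def _w(self, dtype) -> np.ndarray:
        w = self.weight.value
        return w if w.dtype == dtype else w.astype(dtype)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        if k == 1 and p == 0:
            # pointwise fast path: no im2col needed
            xs = x[:, :, ::s, ::s] if s > 1 else x
            y = np.tensordot(self._w(x.dtype)[:, :, 0, 0], xs, axes=([1], [1]))
            y = np.ascontiguousarray(y.transpose(1, 0, 2, 3))
            if train:
                self._cache = (xs, x.shape)
        else:
            cols, (oh, ow) = _im2col(x, k, s, p)
            w2 = self._w(x.dtype).reshape(self.out_channels, -1)
            y = np.matmul(w2, cols)  # (n, cout, oh*ow)
            y = y.reshape(x.shape[0], self.out_channels, oh, ow)
            if train:
                self._cache = (cols, x.shape)
        if self.bias is not None:
            y += self.bias.value.astype(x.dtype)[None, :, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        saved, xshape = self._cache
        self._cache = None
        n, cout = dy.shape[0], dy.shape[1]
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        if k == 1 and p == 0:
            xs = saved
            self.weight.grad += np.tensordot(dy, xs, axes=([0, 2, 3], [0, 2, 3]))[
                :, :, None, None
            ]
            dxs = np.tensordot(self._w(dy.dtype)[:, :, 0, 0], dy, axes=([0], [1]))
            dxs = dxs.transpose(1, 0, 2, 3)
            if s == 1:
                return np.ascontiguousarray(dxs)
            dx = np.zeros(xshape, dtype=dy.dtype)
            dx[:, :, ::s, ::s] = dxs
            return dx
        cols = saved
        dy2 = dy.reshape(n, cout, -1)
        self.weight.grad += np.tensordot(dy2, cols, axes=([0, 2], [0, 2])).reshape(
            self.weight.value.shape
        )
        w2 = self._w(dy.dtype).reshape(cout, -1)
        dcols = np.matmul(w2.T, dy2)
        return _col2im(dcols, xshape, k, s, p)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "bn"):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean = self.running_mean
            var = self.running_var
        std = np.sqrt(var + self.eps).astype(x.dtype)
        xhat = (x - mean.astype(x.dtype)[None, :, None, None]) / std[None, :, None, None]
        y = self.gamma.value.astype(x.dtype)[None, :, None, None] * xhat
        y += self.beta.value.astype(x.dtype)[None, :, None, None]
        if train:
            self._cache = (xhat, std)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        axes = (0, 2, 3)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += np.sum(dy * xhat, axis=axes)
        self.beta.grad += np.sum(dy, axis=axes)
        g = self.gamma.value.astype(dy.dtype)[None, :, None, None]
        dxhat = dy * g
        # standard batch-norm backward over the batch+spatial axes
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / m
        ) / std[None, :, None, None]
        self._cache = None
        return dx


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class Sigmoid(Module):
    def __init__(self):
        self._out = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        if train:
            self._out = out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._out * (1.0 - self._out)
        self._out = None
        return dx


class MaxPool2d(Module):
    """k x k max pooling (ResNet stem uses 3x3, stride 2, pad 1)."""

    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        cols, (oh, ow) = _im2col(x, k, s, p, pad_value=-np.inf)
        n, c = x.shape[:2]
        cols = cols.reshape(n, c, k * k, oh * ow)
        idx = np.argmax(cols, axis=2)
        y = np.take_along_axis(cols, idx[:, :, None, :], axis=2)[:, :, 0, :]
        if train:
            self._cache = (idx, x.shape, (oh, ow))
        return y.reshape(n, c, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, xshape, (oh, ow) = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        n, c = xshape[:2]
        dcols = np.zeros((n, c, k * k, oh * ow), dtype=dy.dtype)
        np.put_along_axis(dcols, idx[:, :, None, :], dy.reshape(n, c, 1, -1), axis=2)
        self._cache = None
        return _col2im(dcols.reshape(n, c * k * k, oh * ow), xshape, k, s, p)


class UpsampleNearest2d(Module):
    """Nearest-neighbour up-sampling by an integer factor (default x2)."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.factor
        return np.repeat(np.repeat(x, f, axis=2), f, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self.factor
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // f, f, w // f, f).sum(axis=(3, 5))


class Adam:
    """Adam optimizer over a parameter list; frozen params are skipped."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if not p.trainable:
                continue
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
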