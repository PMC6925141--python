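"""Minimal CPU neural-network engine (numpy, forward + backward).

Implements exactly the layer set the slice classifier needs: 2D
convolution (im2col), batch normalization, ReLU, max/average pooling,
inverted dropout, a fully connected head, softmax cross-entropy, and SGD
with momentum, weight decay and a reduce-on-plateau learning-rate
schedule. Everything is float64 and seed-deterministic: given the same
seed and data, training histories are bitwise reproducible on a single
thread.

Tensors are NCHW (batch, channel, height, width).
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its gradient and momentum buffer."""

    __slots__ = ("value", "grad", "momentum", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.momentum = np.zeros_like(value)
        self.decay = decay  # weight decay applies to weights, not BN/bias


class Module:
    """Base class: caches forward inputs, exposes params recursively."""

    def params(self) -> List[Param]:
        out: List[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def modules(self) -> List["Module"]:
        out: List[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


# ---------------------------------------------------------------- im2col

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Return column tensor (N, C, kh, kw, OH, OW) of sliding windows."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # N,C,H',W',kh,kw
    win = win[:, :, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))


def _col2im(dcols: np.ndarray, x_shape, kh, kw, stride, pad) -> np.ndarray:
    """Scatter-add columns (N, C, kh, kw, OH, OW) back to an image."""
    n, c, h, w = x_shape
    oh, ow = dcols.shape[-2:]
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


def conv_out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


# ----------------------------------------------------------------- layers

class Conv2d(Module):
    """2D convolution (cross-correlation), He-normal initialized, no bias.

    Biases are omitted because every convolution here is followed by (or
    preceded by, in pre-activation blocks) a batch normalization whose
    shift parameter absorbs them.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 pad: Optional[int] = None, rng: Optional[np.random.Generator] = None,
                 is_projection: bool = False):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * k * k
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, k, k)))
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.is_projection = is_projection
        self._cache = None

    def forward(self, x, train):
        cols = _im2col(x, self.k, self.k, self.stride, self.pad)
        n, c, kh, kw, oh, ow = cols.shape
        cols2 = cols.reshape(n, c * kh * kw, oh * ow)
        w2 = self.weight.value.reshape(self.weight.value.shape[0], -1)
        out = np.einsum("fk,nkp->nfp", w2, cols2, optimize=True)
        self._cache = (x.shape, cols2, (oh, ow))
        return out.reshape(n, -1, oh, ow)

    def backward(self, gout):
        x_shape, cols2, (oh, ow) = self._cache
        n = gout.shape[0]
        f = gout.shape[1]
        g2 = gout.reshape(n, f, oh * ow)
        self.weight.grad += np.einsum("nfp,nkp->fk", g2, cols2, optimize=True).reshape(
            self.weight.value.shape
        )
        w2 = self.weight.value.reshape(f, -1)
        dcols2 = np.einsum("fk,nfp->nkp", w2, g2, optimize=True)
        c = x_shape[1]
        dcols = dcols2.reshape(n, c, self.k, self.k, oh, ow)
        return _col2im(dcols, x_shape, self.k, self.k, self.stride, self.pad)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(n_ch), decay=False)
        self.beta = Param(np.zeros(n_ch), decay=False)
        self.eps, self.bn_momentum = eps, momentum
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self._cache = None

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.bn_momentum * (mean - self.running_mean)
            self.running_var += self.bn_momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, train)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, gout):
        xhat, std, train = self._cache
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        g = gout * self.gamma.value[None, :, None, None]
        if not train:
            return g / std[None, :, None, None]
        m = gout.shape[0] * gout.shape[2] * gout.shape[3]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (g - gsum / m - xhat * gxsum / m) / std[None, :, None, None]


class ReLU(Module):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class MaxPool2d(Module):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x, train):
        cols = _im2col(x, self.k, self.k, self.stride, self.pad)
        n, c, kh, kw, oh, ow = cols.shape
        flat = cols.reshape(n, c, kh * kw, oh, ow)
        arg = flat.argmax(axis=2)
        out = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]
        self._cache = (x.shape, arg, (n, c, kh, kw, oh, ow))
        return out

    def backward(self, gout):
        x_shape, arg, (n, c, kh, kw, oh, ow) = self._cache
        dflat = np.zeros((n, c, kh * kw, oh, ow))
        np.put_along_axis(dflat, arg[:, :, None], gout[:, :, None], axis=2)
        return _col2im(dflat.reshape(n, c, kh, kw, oh, ow), x_shape,
                       self.k, self.k, self.stride, self.pad)


class AvgPool2d(Module):
    def __init__(self, k: int, stride: Optional[int] = None, pad: int = 0):
        self.k, self.stride, self.pad = k, stride or k, pad
        self._cache = None

    def forward(self, x, train):
        k = min(self.k, x.shape[2], x.shape[3])  # window never exceeds input
        cols = _im2col(x, k, k, self.stride, self.pad)
        n, c, kh, kw, oh, ow = cols.shape
        self._cache = (x.shape, k, (oh, ow))
        return cols.mean(axis=(2, 3))

    def backward(self, gout):
        x_shape, k, (oh, ow) = self._cache
        n, c = x_shape[:2]
        dcols = np.broadcast_to(
            gout[:, :, None, None] / (k * k), (n, c, k, k, oh, ow)
        )
        return _col2im(dcols, x_shape, k, k, self.stride, self.pad)


class Dropout(Module):
    """Inverted dropout; ``rate`` is the drop probability."""

    def __init__(self, rate: float, rng: Optional[np.random.Generator] = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / in_f), (out_f, in_f)))
        self.bias = Param(np.zeros(out_f), decay=False)
        self._x = None

    def forward(self, x, train):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, gout):
        self.weight.grad += gout.T @ self._x
        self.bias.grad += gout.sum(axis=0)
        return gout @ self.weight.value


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray,
                  class_weights: Optional[np.ndarray] = None):
    """Mean cross-entropy of softmax(logits) vs integer labels, with grad.

    With two classes this is binary cross-entropy on the positive-class
    probability. Returns ``(loss, dlogits)``.
    """
    n = logits.shape[0]
    p = softmax(logits)
    w = np.ones(n) if class_weights is None else class_weights[labels]
    ll = -np.log(np.maximum(p[np.arange(n), labels], 1e-12))
    loss = float((w * ll).sum() / w.sum())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= (w / w.sum())[:, None]
    return loss, dlogits


# ------------------------------------------------------------- optimizer

class SGD:
    """SGD with classical momentum and decoupled L2 weight decay."""

    def __init__(self, params: List[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p in self.params:
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            p.momentum[...] = self.momentum * p.momentum + g
            p.value -= self.lr * p.momentum


class ReduceLROnPlateau:
    """Divide the learning rate by ``factor`` when a monitored loss stalls."""

    def __init__(self, optimizer: SGD, factor: float = 10.0, patience: int = 5,
                 min_lr: float = 1e-8):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.stale = 0

    def step(self, monitored: float) -> None:
        if monitored < self.best - 1e-12:
            self.best = monitored
            self.stale = 0
        else:
            self.stale += 1
            if self.stale > self.patience:
                self.optimizer.lr = max(self.optimizer.lr / self.factor, self.min_lr)
                self.stale = 0
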