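"""Minimal CPU neural-network primitives (forward + manual backprop).

Layers operate on float32 arrays in (N, C, *spatial) layout and cache what
their backward pass needs. Convolutions use kernel-offset gather/scatter
(im2col by small fixed loops), which keeps memory bounded and vectorises
the heavy lifting through BLAS matmuls. Only what the residual classifiers
need is implemented: grouped 2D/3D convolution, batch norm, ReLU, max and
global-average pooling, a dense head, and softmax cross-entropy.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    training: bool = True

    def params(self) -> list[Param]:
        out = []
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

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.set_training(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_out), size=shape).astype(np.float32)


class ConvNd(Module):
    """Grouped n-dimensional convolution (n = 2 or 3), no bias (BN follows)."""

    def __init__(
        self,
        ndim: int,
        in_ch: int,
        out_ch: int,
        kernel: int | tuple[int, ...],
        stride: int | tuple[int, ...] = 1,
        padding: int | tuple[int, ...] = 0,
        groups: int = 1,
        rng: np.random.Generator | None = None,
    ):
        self.ndim = ndim
        if isinstance(kernel, int):
            kernel = (kernel,) * ndim
        if isinstance(stride, int):
            stride = (stride,) * ndim
        if isinstance(padding, int):
            padding = (padding,) * ndim
        if in_ch % groups or out_ch % groups:
            raise ValueError(f"groups={groups} must divide in_ch={in_ch} and out_ch={out_ch}")
        self.kernel, self.stride, self.padding, self.groups = kernel, stride, padding, groups
        self.in_ch, self.out_ch = in_ch, out_ch
        rng = rng or np.random.default_rng()
        fan_out = out_ch * int(np.prod(kernel)) // groups
        self.weight = Param(
            _he_init(rng, (out_ch, in_ch // groups) + tuple(kernel), fan_out)
        )

    def _out_shape(self, spatial: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(
            (s + 2 * p - k) // st + 1
            for s, k, st, p in zip(spatial, self.kernel, self.stride, self.padding)
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        out_sp = self._out_shape(spatial)
        pad = [(0, 0), (0, 0)] + [(p, p) for p in self.padding]
        xp = np.pad(x, pad) if any(self.padding) else x
        # gather columns: (N, C, prod(kernel), prod(out_sp))
        cols = np.empty((n, c, int(np.prod(self.kernel)), int(np.prod(out_sp))), dtype=np.float32)
        for ki, off in enumerate(np.ndindex(*self.kernel)):
            sl = tuple(
                slice(o, o + st * os, st) for o, st, os in zip(off, self.stride, out_sp)
            )
            cols[:, :, ki, :] = xp[(slice(None), slice(None)) + sl].reshape(n, c, -1)
        g, cg, og = self.groups, c // self.groups, self.out_ch // self.groups
        k = int(np.prod(self.kernel))
        cols_g = cols.reshape(n, g, cg * k, -1)
        w = self.weight.value.reshape(g, og, cg * k)
        out = np.einsum("gok,ngkl->ngol", w, cols_g, optimize=True)
        self._cache = (cols_g, x.shape, xp.shape)
        return np.ascontiguousarray(out.reshape(n, self.out_ch, *out_sp))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols_g, x_shape, xp_shape = self._cache
        n = grad.shape[0]
        out_sp = grad.shape[2:]
        g, og = self.groups, self.out_ch // self.groups
        cg = self.in_ch // self.groups
        k = int(np.prod(self.kernel))
        gflat = grad.reshape(n, g, og, -1)
        w = self.weight.value.reshape(g, og, cg * k)
        self.weight.grad += np.einsum("ngol,ngkl->gok", gflat, cols_g, optimize=True).reshape(
            self.weight.value.shape
        )
        dcols = np.einsum("gok,ngol->ngkl", w, gflat, optimize=True).reshape(
            n, self.in_ch, k, -1
        )
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for ki, off in enumerate(np.ndindex(*self.kernel)):
            sl = tuple(
                slice(o, o + st * os, st) for o, st, os in zip(off, self.stride, out_sp)
            )
            dxp[(slice(None), slice(None)) + sl] += dcols[:, :, ki, :].reshape(
                (n, self.in_ch) + tuple(out_sp)
            )
        if any(self.padding):
            sl = tuple(slice(p, s + p) for p, s in zip(self.padding, x_shape[2:]))
            return dxp[(slice(None), slice(None)) + sl]
        return dxp


class BatchNorm(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_ch, dtype=np.float32))
        self.beta = Param(np.zeros(n_ch, dtype=np.float32))
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def _bshape(self, x: np.ndarray) -> tuple[int, ...]:
        return (1, x.shape[1]) + (1,) * (x.ndim - 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        shp = self._bshape(x)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv.reshape(shp)
        self._cache = (xhat, inv, axes, x.shape)
        return self.gamma.value.reshape(shp) * xhat + self.beta.value.reshape(shp)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, axes, x_shape = self._cache
        shp = self._bshape(grad)
        m = float(np.prod([x_shape[a] for a in axes]))
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value.reshape(shp)
        if not self.training:
            return g * inv.reshape(shp)
        gsum = g.sum(axis=axes, keepdims=True)
        gx_sum = (g * xhat).sum(axis=axes, keepdims=True)
        return (inv.reshape(shp) / m) * (m * g - gsum - xhat * gx_sum)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class MaxPoolNd(Module):
    """Max pooling via kernel-offset stacking (kernel 3, stride 2, pad 1 typical)."""

    def __init__(self, ndim: int, kernel: int = 3, stride: int = 2, padding: int = 1):
        self.ndim = ndim
        self.kernel = (kernel,) * ndim
        self.stride = (stride,) * ndim
        self.padding = (padding,) * ndim

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c = x.shape[:2]
        out_sp = tuple(
            (s + 2 * p - k) // st + 1
            for s, k, st, p in zip(x.shape[2:], self.kernel, self.stride, self.padding)
        )
        pad = [(0, 0), (0, 0)] + [(p, p) for p in self.padding]
        xp = np.pad(x, pad, constant_values=-np.inf)
        k = int(np.prod(self.kernel))
        cols = np.empty((n, c, k, int(np.prod(out_sp))), dtype=np.float32)
        for ki, off in enumerate(np.ndindex(*self.kernel)):
            sl = tuple(slice(o, o + st * os, st) for o, st, os in zip(off, self.stride, out_sp))
            cols[:, :, ki, :] = xp[(slice(None), slice(None)) + sl].reshape(n, c, -1)
        self._argmax = cols.argmax(axis=2)
        self._shapes = (x.shape, xp.shape, out_sp)
        return cols.max(axis=2).reshape((n, c) + out_sp)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, out_sp = self._shapes
        n, c = grad.shape[:2]
        gflat = grad.reshape(n, c, -1)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for ki, off in enumerate(np.ndindex(*self.kernel)):
            sl = tuple(slice(o, o + st * os, st) for o, st, os in zip(off, self.stride, out_sp))
            contrib = np.where(self._argmax == ki, gflat, 0.0).reshape((n, c) + out_sp)
            dxp[(slice(None), slice(None)) + sl] += contrib
        sl = tuple(slice(p, s + p) for p, s in zip(self.padding, x_shape[2:]))
        return dxp[(slice(None), slice(None)) + sl]


class GlobalAvgPool(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        shape = self._shape
        m = float(np.prod(shape[2:]))
        g = grad.reshape(shape[:2] + (1,) * (len(shape) - 2))
        return np.broadcast_to(g / m, shape).astype(np.float32)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.weight = Param(rng.normal(0.0, np.sqrt(1.0 / in_f), (out_f, in_f)))
        self.bias = Param(np.zeros(out_f, dtype=np.float32))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(
    logits: np.ndarray, labels: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean 2-class cross-entropy over softmax; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=np.float64)
    wsum = w.sum()
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    loss = float((w * nll).sum() / wsum)
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits.astype(np.float32)


class SGD:
    """Plain stochastic gradient descent with decoupled-style L2 weight decay."""

    def __init__(self, params: list[Param], lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p in self.params:
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            p.value -= self.lr * g
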