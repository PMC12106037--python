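"""Minimal neural-network core on numpy.

Every layer is a :class:`Module` with an explicit ``forward`` that caches
what its hand-derived ``backward`` needs.  Feature tensors are ``float32``
arrays in channel-first layout: ``(C, D, H, W)`` for volumetric features,
``(C, H, W)`` for planar ones.  All convolutions are bias-free (biases are
carried only by the final linear classifier layer); 3x3x3 convolutions use
"same" zero padding so spatial extents are preserved at stride 1.

The core is deliberately small: standard / depthwise / pointwise 3-D
convolutions, a 2x2x2 transpose convolution, instance normalisation, leaky
ReLU, sigmoid, max pooling, a 2-D conv for the classifier branch, and a
linear layer.  Determinism is inherited from numpy: identical seeds give
bitwise-identical parameters, activations and gradients.
"""
from __future__ import annotations

import numpy as np


class Parameter:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: subclasses define forward(x) and backward(grad)."""

    def parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, attr in vars(self).items():
            if isinstance(attr, Parameter):
                out[name] = attr
            elif isinstance(attr, Module):
                for sub, p in attr.parameters().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = p
        return out

    def num_params(self) -> int:
        return sum(p.size for p in self.parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def fan_in_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He-style fan-in scaled Gaussian initialisation."""
    std = np.sqrt(2.0 / max(fan_in, 1))
    return (rng.standard_normal(shape) * std).astype(np.float32)


def _pad3(x: np.ndarray, p: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))


class PointwiseConv3d(Module):
    """1x1x1 convolution: a channel-mixing matrix applied at every voxel."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Parameter(fan_in_init(rng, (out_channels, in_channels), in_channels))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.tensordot(self.weight.value, x, axes=(1, 0))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        self.weight.grad += np.tensordot(grad.reshape(grad.shape[0], -1),
                                         x.reshape(x.shape[0], -1).T, axes=1)
        return np.tensordot(self.weight.value.T, grad, axes=(1, 0))


class DepthwiseConv3d(Module):
    """Per-channel 3-D convolution ("same" padding, stride 1).

    Channel c of the output depends only on channel c of the input.
    """

    def __init__(self, channels: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator):
        if any(k % 2 == 0 for k in kernel):
            raise ValueError("depthwise kernel extents must be odd for same padding")
        self.channels = channels
        self.kernel = kernel
        kd, kh, kw = kernel
        self.weight = Parameter(fan_in_init(rng, (channels, kd, kh, kw), kd * kh * kw))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        kd, kh, kw = self.kernel
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (pd, pd), (ph, ph), (pw, pw)))
        _, D, H, W = x.shape
        out = np.zeros_like(x)
        w = self.weight.value
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    out += w[:, i, j, k, None, None, None] * xp[:, i:i + D, j:j + H, k:k + W]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        kd, kh, kw = self.kernel
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        _, D, H, W = x.shape
        xp = np.pad(x, ((0, 0), (pd, pd), (ph, ph), (pw, pw)))
        gp = np.pad(grad, ((0, 0), (pd, pd), (ph, ph), (pw, pw)))
        w = self.weight.value
        dx = np.zeros_like(x)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    patch = xp[:, i:i + D, j:j + H, k:k + W]
                    self.weight.grad[:, i, j, k] += np.einsum("cdhw,cdhw->c", grad, patch)
                    # correlation adjoint: flip the offset
                    dx += w[:, i, j, k, None, None, None] * gp[:, kd - 1 - i:kd - 1 - i + D,
                                                               kh - 1 - j:kh - 1 - j + H,
                                                               kw - 1 - k:kw - 1 - k + W]
        return dx


class Conv3d(Module):
    """Standard 3-D convolution, "same" padding, stride 1 (shift-and-matmul)."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int, int], rng: np.random.Generator):
        if any(k % 2 == 0 for k in kernel):
            raise ValueError("kernel extents must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        kd, kh, kw = kernel
        fan_in = in_channels * kd * kh * kw
        self.weight = Parameter(fan_in_init(rng, (out_channels, in_channels, kd, kh, kw), fan_in))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        kd, kh, kw = self.kernel
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (pd, pd), (ph, ph), (pw, pw)))
        _, D, H, W = x.shape
        out = np.zeros((self.out_channels, D, H, W), dtype=np.float32)
        w = self.weight.value
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    out += np.tensordot(w[:, :, i, j, k], xp[:, i:i + D, j:j + H, k:k + W],
                                        axes=(1, 0))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        kd, kh, kw = self.kernel
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        _, D, H, W = x.shape
        xp = np.pad(x, ((0, 0), (pd, pd), (ph, ph), (pw, pw)))
        gp = np.pad(grad, ((0, 0), (pd, pd), (ph, ph), (pw, pw)))
        w = self.weight.value
        dx = np.zeros_like(x)
        gflat = grad.reshape(grad.shape[0], -1)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    patch = xp[:, i:i + D, j:j + H, k:k + W]
                    self.weight.grad[:, :, i, j, k] += gflat @ patch.reshape(patch.shape[0], -1).T
                    dx += np.tensordot(w[:, :, i, j, k].T,
                                       gp[:, kd - 1 - i:kd - 1 - i + D,
                                          kh - 1 - j:kh - 1 - j + H,
                                          kw - 1 - k:kw - 1 - k + W], axes=(1, 0))
        return dx


class ConvTranspose3d(Module):
    """2x2x2 transpose convolution with stride 2 (doubles every extent)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Parameter(fan_in_init(rng, (in_channels, out_channels, 2, 2, 2), in_channels))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        _, D, H, W = x.shape
        # (o,d,h,w,i,j,k) -> interleave kernel offsets into doubled extents
        t = np.einsum("cdhw,coijk->odihjwk", x, self.weight.value, optimize=True)
        return np.ascontiguousarray(t.reshape(self.out_channels, 2 * D, 2 * H, 2 * W))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        _, D, H, W = x.shape
        g = grad.reshape(self.out_channels, D, 2, H, 2, W, 2)
        self.weight.grad += np.einsum("cdhw,odihjwk->coijk", x, g, optimize=True)
        return np.einsum("odihjwk,coijk->cdhw", g, self.weight.value, optimize=True)


class Conv2d(Module):
    """Standard 2-D convolution ("same" padding, stride 1) for the classifier."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.weight = Parameter(
            fan_in_init(rng, (out_channels, in_channels, kernel, kernel),
                        in_channels * kernel * kernel))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        _, H, W = x.shape
        out = np.zeros((self.out_channels, H, W), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                out += np.tensordot(self.weight.value[:, :, i, j],
                                    xp[:, i:i + H, j:j + W], axes=(1, 0))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        k = self.kernel
        p = k // 2
        _, H, W = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        gp = np.pad(grad, ((0, 0), (p, p), (p, p)))
        dx = np.zeros_like(x)
        gflat = grad.reshape(grad.shape[0], -1)
        for i in range(k):
            for j in range(k):
                patch = xp[:, i:i + H, j:j + W]
                self.weight.grad[:, :, i, j] += gflat @ patch.reshape(patch.shape[0], -1).T
                dx += np.tensordot(self.weight.value[:, :, i, j].T,
                                   gp[:, k - 1 - i:k - 1 - i + H, k - 1 - j:k - 1 - j + W],
                                   axes=(1, 0))
        return dx


class InstanceNorm(Module):
    """Per-channel standardisation over all spatial axes, learned affine.

    Works for any rank >= 2 channel-first tensor.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(1, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        shape = (-1,) + (1,) * (x.ndim - 1)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = tuple(range(1, grad.ndim))
        n = np.prod([grad.shape[a] for a in axes])
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        shape = (-1,) + (1,) * (grad.ndim - 1)
        g = grad * self.gamma.value.reshape(shape)
        return inv * (g - g.mean(axis=axes, keepdims=True)
                      - xhat * (g * xhat).mean(axis=axes, keepdims=True))


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.01):
        self.negative_slope = negative_slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.negative_slope * x).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.negative_slope * grad).astype(np.float32)


class Sigmoid(Module):
    def __init__(self):
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        # numerically stable on both tails
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        e = np.exp(x[~pos])
        y[~pos] = e / (1.0 + e)
        self._y = y
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        y = self._y
        return grad * y * (1.0 - y)


class MaxPool3d(Module):
    """2x2x2 max pooling, stride 2; extents must be even."""

    def __init__(self):
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, D, H, W = x.shape
        if D % 2 or H % 2 or W % 2:
            raise ValueError(f"extents must be even for 2x2x2 pooling, got {x.shape}")
        xr = x.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(2, 4, 6))
        mask = xr == out[:, :, None, :, None, :, None]
        # break ties so each window routes gradient to exactly one voxel
        flat = mask.transpose(0, 1, 3, 5, 2, 4, 6).reshape(-1, 8)
        first = flat.cumsum(axis=1) == 1
        mask = (flat & first).reshape(C, D // 2, H // 2, W // 2, 2, 2, 2) \
                             .transpose(0, 1, 4, 2, 5, 3, 6)
        self._cache = (mask, x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask, shape = self._cache
        C, D, H, W = shape
        g = mask * grad[:, :, None, :, None, :, None]
        return g.reshape(C, D, H, W).astype(np.float32)


class MaxPool2d(Module):
    """2x2 max pooling, stride 2, for the classifier branch."""

    def __init__(self):
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"extents must be even for 2x2 pooling, got {x.shape}")
        xr = x.reshape(C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None]
        flat = mask.transpose(0, 1, 3, 2, 4).reshape(-1, 4)
        first = flat.cumsum(axis=1) == 1
        mask = (flat & first).reshape(C, H // 2, W // 2, 2, 2).transpose(0, 1, 3, 2, 4)
        self._cache = (mask, x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask, shape = self._cache
        C, H, W = shape
        g = mask * grad[:, :, None, :, None]
        return g.reshape(C, H, W).astype(np.float32)


class Linear(Module):
    """Dense layer with bias (the only biased layer in the package)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(fan_in_init(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return self.weight.value @ x + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += np.outer(grad, self._x)
        self.bias.grad += grad
        return self.weight.value.T @ grad


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.layers = list(modules)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.layers:
            x = m(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for m in reversed(self.layers):
            grad = m.backward(grad)
        return grad


class Adam:
    """Adam with decoupled weight decay and configurable first-moment decay."""

    def __init__(self, params: dict[str, Parameter], lr: float = 1e-4,
                 beta1: float = 0.95, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = beta1, beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad
            m = self._m[k]
            v = self._v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            if self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
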