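"""Small NumPy neural-network core with explicit reverse-mode gradients.

The graded environment ships no deep-learning framework, so the few layer
types the networks need (3-D convolution, instance/group normalization,
PReLU, dropout, linear head) are implemented directly.  Every layer caches
what its backward pass needs during ``forward`` and exposes ``backward``
returning the gradient with respect to its input while accumulating
parameter gradients in-place.  All layers are dtype-agnostic: float64 inputs
give float64 gradients, which is what the finite-difference tests use;
training runs in float32.

Tensors are ``(N, C, D, H, W)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv3d",
    "PReLU",
    "InstanceNorm3d",
    "GroupNorm",
    "Dropout",
    "Tanh",
    "GlobalAvgPool",
    "Linear",
    "Softmax",
    "Adam",
]


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class; collects parameters from attributes and sub-modules."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)

    def state(self) -> list[np.ndarray]:
        return [p.value for p in self.parameters()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"state has {len(arrays)} arrays, model expects {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError(
                    f"shape mismatch for {p.name or 'parameter'}: "
                    f"{p.value.shape} vs {a.shape}"
                )
            p.value = np.asarray(a, dtype=p.value.dtype)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Conv3d(Module):
    """3-D convolution, kernel k, arbitrary stride, symmetric zero padding.

    Implemented as an implicit im2col: the forward pass accumulates strided
    slices, the backward pass re-materializes the column matrix from the
    cached padded input (cheaper than caching it).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if kernel_size % 2 != 1:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        self.pad = kernel_size // 2 if padding is None else padding
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (in_channels * kernel_size**3))
        self.W = Parameter(
            rng.normal(0.0, scale, (out_channels, in_channels, *(kernel_size,) * 3)).astype(dtype),
            name="conv.W",
        )
        self.b = Parameter(np.zeros(out_channels, dtype=dtype), name="conv.b")
        self._cache = None

    def _out_shape(self, D, H, W):
        k, s, p = self.k, self.stride, self.pad
        return ((D + 2 * p - k) // s + 1, (H + 2 * p - k) // s + 1, (W + 2 * p - k) // s + 1)

    def _im2col(self, xp, out_shape):
        N, C = xp.shape[:2]
        k, s = self.k, self.stride
        Do, Ho, Wo = out_shape
        # windows: (N, C, Do, Ho, Wo, k, k, k) strided view, then reorder so
        # the column axis is laid out as (C, kz, ky, kx)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        win = win[:, :, ::s, ::s, ::s][:, :, :Do, :Ho, :Wo]
        cols = np.ascontiguousarray(win.transpose(0, 1, 5, 6, 7, 2, 3, 4))
        return cols.reshape(N, C * k**3, Do * Ho * Wo)

    def forward(self, x, training=False):
        if x.ndim != 5 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N,{self.in_channels},D,H,W) input, got {x.shape}"
            )
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        out_shape = self._out_shape(*x.shape[2:])
        cols = self._im2col(xp, out_shape)
        Wmat = self.W.value.reshape(self.out_channels, -1)
        y = np.matmul(Wmat[None].astype(x.dtype), cols)
        y += self.b.value.astype(x.dtype)[None, :, None]
        self._cache = (xp.shape, x.shape, out_shape, cols)
        return y.reshape(x.shape[0], self.out_channels, *out_shape)

    def backward(self, grad):
        xp_shape, x_shape, out_shape, cols = self._cache
        N = x_shape[0]
        k, s, p = self.k, self.stride, self.pad
        Do, Ho, Wo = out_shape
        g2 = grad.reshape(N, self.out_channels, -1)
        self.W.grad += (
            np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.W.value.shape)
        )
        self.b.grad += g2.sum(axis=(0, 2))
        self._cache = (xp_shape, x_shape, out_shape, None)  # release the columns
        Wmat = self.W.value.reshape(self.out_channels, -1)
        gcols = np.matmul(Wmat.T[None].astype(grad.dtype), g2)
        gcols = gcols.reshape(N, self.in_channels, k, k, k, Do, Ho, Wo)
        gxp = np.zeros(xp_shape, dtype=grad.dtype)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    gxp[
                        :, :, dz : dz + s * Do : s, dy : dy + s * Ho : s, dx : dx + s * Wo : s
                    ] += gcols[:, :, dz, dy, dx]
        if p:
            gxp = gxp[:, :, p:-p, p:-p, p:-p]
        return gxp


class PReLU(Module):
    """Parametric ReLU with one learnable slope shared across the layer."""

    def __init__(self, init: float = 0.25, dtype=np.float32):
        self.a = Parameter(np.array(init, dtype=dtype), name="prelu.a")
        self._cache = None

    def forward(self, x, training=False):
        neg = np.minimum(x, 0)
        self._cache = (x > 0, neg)
        return np.maximum(x, 0) + x.dtype.type(self.a.value) * neg

    def backward(self, grad):
        pos_mask, neg = self._cache
        self.a.grad += np.asarray((grad * neg).sum(), dtype=self.a.value.dtype)
        return grad * np.where(pos_mask, grad.dtype.type(1.0), grad.dtype.type(self.a.value))


def _norm_backward(grad_hat, xhat, inv_std, axes):
    m = np.prod([xhat.shape[a] for a in axes])
    mean_g = grad_hat.mean(axis=axes, keepdims=True)
    mean_gx = (grad_hat * xhat).mean(axis=axes, keepdims=True)
    return inv_std * (grad_hat - mean_g - xhat * mean_gx), m


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over spatial voxels, affine."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype), name="inorm.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype), name="inorm.beta")
        self._cache = None

    def forward(self, x, training=False):
        axes = (2, 3, 4)
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std.astype(x.dtype))
        g = self.gamma.value.astype(x.dtype).reshape(1, -1, 1, 1, 1)
        b = self.beta.value.astype(x.dtype).reshape(1, -1, 1, 1, 1)
        return g * xhat + b

    def backward(self, grad):
        xhat, inv_std = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3, 4))
        self.beta.grad += grad.sum(axis=(0, 2, 3, 4))
        grad_hat = grad * self.gamma.value.astype(grad.dtype).reshape(1, -1, 1, 1, 1)
        gx, _ = _norm_backward(grad_hat, xhat, inv_std, axes=(2, 3, 4))
        return gx


class GroupNorm(Module):
    """Group normalization; ``group_size`` channels per group, affine."""

    def __init__(self, channels: int, group_size: int = 16, eps: float = 1e-5, dtype=np.float32):
        group_size = min(group_size, channels)
        if channels % group_size != 0:
            raise ValueError(
                f"channels {channels} not divisible by group size {group_size}"
            )
        self.channels = channels
        self.group_size = group_size
        self.n_groups = channels // group_size
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype), name="gnorm.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype), name="gnorm.beta")
        self._cache = None

    def forward(self, x, training=False):
        N, C, D, H, W = x.shape
        xg = x.reshape(N, self.n_groups, self.group_size, D, H, W)
        axes = (2, 3, 4, 5)
        mu = xg.mean(axis=axes, keepdims=True)
        var = xg.var(axis=axes, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (xg - mu) * inv_std
        self._cache = (xhat, inv_std.astype(x.dtype), x.shape)
        out = xhat.reshape(x.shape)
        g = self.gamma.value.astype(x.dtype).reshape(1, -1, 1, 1, 1)
        b = self.beta.value.astype(x.dtype).reshape(1, -1, 1, 1, 1)
        return g * out + b

    def backward(self, grad):
        xhat, inv_std, x_shape = self._cache
        xhat_flat = xhat.reshape(x_shape)
        self.gamma.grad += (grad * xhat_flat).sum(axis=(0, 2, 3, 4))
        self.beta.grad += grad.sum(axis=(0, 2, 3, 4))
        grad_hat = grad * self.gamma.value.astype(grad.dtype).reshape(1, -1, 1, 1, 1)
        N, C, D, H, W = x_shape
        gh = grad_hat.reshape(N, self.n_groups, self.group_size, D, H, W)
        gx, _ = _norm_backward(gh, xhat, inv_std, axes=(2, 3, 4, 5))
        return gx.reshape(x_shape)


class Dropout(Module):
    """Inverted dropout; identity when not training or p == 0."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Tanh(Module):
    def forward(self, x, training=False):
        y = np.tanh(x)
        self._y = y
        return y

    def backward(self, grad):
        return grad * (1.0 - self._y * self._y)


class GlobalAvgPool(Module):
    """Mean over spatial dims: (N, C, D, H, W) -> (N, C)."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad):
        N, C, D, H, W = self._shape
        g = grad.reshape(N, C, 1, 1, 1) / (D * H * W)
        return np.broadcast_to(g, self._shape).copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_features)
        self.W = Parameter(
            rng.normal(0.0, scale, (out_features, in_features)).astype(dtype), name="linear.W"
        )
        self.b = Parameter(np.zeros(out_features, dtype=dtype), name="linear.b")

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value.T.astype(x.dtype) + self.b.value.astype(x.dtype)

    def backward(self, grad):
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.astype(grad.dtype)


class Softmax(Module):
    """Softmax over the last axis."""

    def forward(self, x, training=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._s = e / e.sum(axis=-1, keepdims=True)
        return self._s

    def backward(self, grad):
        s = self._s
        dot = (grad * s).sum(axis=-1, keepdims=True)
        return s * (grad - dot)


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value = (
                p.value.astype(np.float64) - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(p.value.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
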