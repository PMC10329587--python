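"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the primitives the segmentation pipeline needs — elementwise
arithmetic, matmul, 2D convolution, bilinear resizing, reductions, batch
normalization building blocks — plus thin layer classes (:class:`Conv2d`,
:class:`BatchNorm2d`, :class:`Dropout`) and the RAdam optimizer.  Gradients are
accumulated by a topological backward sweep over the recorded tape.

All computation is CPU numpy; dtype follows the inputs (the training path uses
float32, oracle-precision tests pass float64 and keep it).
"""

from __future__ import annotations

import hashlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "astensor",
    "concat",
    "conv2d",
    "resize_bilinear",
    "Conv2d",
    "BatchNorm2d",
    "Dropout",
    "RAdam",
    "parameter_digest",
    "he_init",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph ------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _coerce(self, other) -> "Tensor":
        """Wrap `other`, casting bare python/0-d scalars to this dtype."""
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.ndim == 0 and arr.dtype != self.data.dtype:
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.shape)
            )

        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent: float):
        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, parents=(self,), backward=bw)

    def __matmul__(self, other):
        other = astensor(other)

        def bw(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    # -- pointwise ----------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def clip(self, lo: float | None, hi: float | None):
        """Clamp; gradient passes only through the in-range region."""
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data >= lo
        if hi is not None:
            mask &= self.data <= hi

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(np.clip(self.data, lo, hi), parents=(self,), backward=bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        shape = self.shape

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, shape))

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bw
        )

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accumulate(g[tuple(idx)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bw,
    )


# ---------------------------------------------------------------------------
# Convolution (shift-stack im2col: kernel-offset slices concatenated along
# channels, so the big copy is contiguous and the matmul is batched)
# ---------------------------------------------------------------------------


def _shift_cols(xp: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int):
    """(N, kh*kw*C, ho, wo) stack of kernel-offset views of the padded input."""
    slices = [
        xp[:, :, di : di + stride * ho : stride, dj : dj + stride * wo : stride]
        for di in range(kh)
        for dj in range(kw)
    ]
    return np.concatenate(slices, axis=1)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2D convolution, x: (N, Cin, H, W), weight: (Cout, Cin, kh, kw)."""
    x = astensor(x)
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input has {cin}, weight expects {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    ho = (xp.shape[2] - kh) // stride + 1
    wo = (xp.shape[3] - kw) // stride + 1
    cols = _shift_cols(xp, kh, kw, stride, ho, wo).reshape(n, kh * kw * cin, ho * wo)
    # weight reordered to (cout, kh*kw*cin) matching the slice stacking order
    wmat = weight.data.transpose(0, 2, 3, 1).reshape(cout, -1)
    out = np.matmul(wmat, cols).reshape(n, cout, ho, wo)
    if bias is not None:
        out += bias.data[None, :, None, None]
    parents = (x, weight) + ((bias,) if bias is not None else ())

    def bw(g):
        gmat = g.reshape(n, cout, ho * wo)
        gw = np.tensordot(gmat, cols, axes=([0, 2], [0, 2]))  # (cout, khkwcin)
        weight._accumulate(
            gw.reshape(cout, kh, kw, cin).transpose(0, 3, 1, 2)
        )
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gcols = np.matmul(wmat.T, gmat).reshape(n, kh * kw, cin, ho, wo)
            gx = np.zeros((n, cin, h + 2 * pad, w + 2 * pad), dtype=g.dtype)
            for di in range(kh):
                for dj in range(kw):
                    gx[:, :, di : di + stride * ho : stride, dj : dj + stride * wo : stride] += (
                        gcols[:, di * kw + dj]
                    )
            if pad:
                gx = gx[:, :, pad:-pad, pad:-pad]
            x._accumulate(gx)

    return Tensor(out, parents=parents, backward=bw)


# ---------------------------------------------------------------------------
# Bilinear resize (align_corners=False convention)
# ---------------------------------------------------------------------------


def _linear_coords(n_in: int, n_out: int):
    """Source indices/weights for 1D linear interpolation at pixel centers."""
    pos = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    pos = np.clip(pos, 0, n_in - 1)
    lo = np.floor(pos).astype(np.intp)
    hi = np.minimum(lo + 1, n_in - 1)
    w_hi = pos - lo
    return lo, hi, w_hi


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) 1D linear interpolation operator at pixel centers."""
    lo, hi, w_hi = _linear_coords(n_in, n_out)
    m = np.zeros((n_out, n_in))
    rows = np.arange(n_out)
    np.add.at(m, (rows, lo), 1.0 - w_hi)
    np.add.at(m, (rows, hi), w_hi)
    return m


def resize_bilinear(x: Tensor | np.ndarray, size: tuple[int, int]) -> Tensor | np.ndarray:
    """Bilinear resize of the trailing two axes to `size` (H, W).

    Sampling at pixel centers: an exact 2x downscale equals 2x2 block
    averaging, an upscale interpolates smoothly.  Works on plain arrays
    (returns an array) or tensors (differentiable).  Implemented as two
    matmuls with 1D interpolation operators (the backward pass is their
    transpose).
    """
    is_tensor = isinstance(x, Tensor)
    xt = astensor(x)
    h_in, w_in = xt.shape[-2], xt.shape[-1]
    h_out, w_out = size
    if (h_in, w_in) == (h_out, w_out):
        return x
    dtype = xt.data.dtype if np.issubdtype(xt.data.dtype, np.floating) else np.float64
    my = _interp_matrix(h_in, h_out).astype(dtype)
    mx_t = _interp_matrix(w_in, w_out).astype(dtype).T

    out = my @ xt.data.astype(dtype) @ mx_t
    if not is_tensor:
        return out

    def bw(g):
        xt._accumulate(my.T @ g @ mx_t.T)

    return Tensor(out, parents=(xt,), backward=bw)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays defining the module (parameters + buffers), in order."""
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        arrays = list(arrays)
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch when loading state")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch when loading state")
            p.data = np.array(a, dtype=p.data.dtype)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = True,
        dtype=np.float32,
    ):
        k = kernel_size
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        fan_in = in_channels * k * k
        self.weight = Parameter(he_init(rng, (out_channels, in_channels, k, k), fan_in, dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel, with running stats."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = self.running_mean.astype(x.data.dtype)[None, :, None, None]
            sd = np.sqrt(self.running_var + self.eps).astype(x.data.dtype)[None, :, None, None]
            xhat = (x - Tensor(mu)) / Tensor(sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Dropout(Module):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator | None) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class RAdam:
    """Rectified Adam (variance-rectified adaptive learning rate).

    Falls back to un-adapted momentum updates while the variance estimate is
    untrustworthy (rectification term rho_t <= 4), as in the original method.
    Weight decay is L2-style (added to the gradient).
    """

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.beta2) - 1.0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2, t = self.beta1, self.beta2, self.t
        b2t = b2**t
        rho_t = self.rho_inf - 2.0 * t * b2t / (1.0 - b2t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data.astype(np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1.0 - b1**t)
            if rho_t > 4.0:
                v_hat = np.sqrt(v / (1.0 - b2t))
                r = np.sqrt(
                    ((rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf)
                    / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t)
                )
                update = r * m_hat / (v_hat + self.eps)
            else:
                update = m_hat
            p.data = p.data - (self.lr * update).astype(p.data.dtype)


def parameter_digest(arrays: Iterable[np.ndarray]) -> str:
    """SHA-256 over the concatenated bytes (and shapes) of all arrays."""
    h = hashlib.sha256()
    for a in arrays:
        h.update(str(a.shape).encode())
        h.update(str(a.dtype).encode())
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()
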