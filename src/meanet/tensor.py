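"""Reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core of the package: a small tape-based autodiff
engine providing exactly the operations the segmentation network needs
(stride-1 "same" convolution, 2x2 max pooling, bilinear x2 upsampling,
batch normalisation, global pooling, pointwise nonlinearities and the
usual arithmetic).  Arrays are float32 by default; every operation
records a backward closure and :meth:`Tensor.backward` walks the tape in
reverse topological order, accumulating gradients into ``.grad``.

The engine is deliberately minimal — no broadcasting rules beyond the
ones the network exercises, no views — which keeps every backward rule
individually testable against finite differences.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DEFAULT_DTYPE = np.float32


def _as_array(x, dtype=None) -> np.ndarray:
    a = np.asarray(x)
    if dtype is None:
        # floating inputs keep their precision; everything else becomes
        # the default compute dtype
        dtype = a.dtype if a.dtype.kind == "f" else DEFAULT_DTYPE
    a = np.asarray(a, dtype=dtype)
    return a if a.ndim == 0 else np.ascontiguousarray(a)


class Tensor:
    """An n-d array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None,
                 name: str = ""):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs are deep for long nets
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2,
                                               other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _wrap(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accumulate(self.data.swapaxes(-1, -2) @ g)

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __matmul__ = matmul

    # -- reshaping ------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(src_shape))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bwd)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = self.data * mask

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        s = np.empty_like(self.data)
        pos = self.data >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        e = np.exp(self.data[~pos])
        s[~pos] = e / (1.0 + e)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return Tensor(s, parents=(self,), backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def clip(self, lo: float, hi: float) -> "Tensor":
        inside = (self.data > lo) & (self.data < hi)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * inside)

        return Tensor(np.clip(self.data, lo, hi), parents=(self,), backward=bwd)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to ``shape`` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (channel axis by default)."""
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


# ----------------------------------------------------------------------
# Convolution (stride 1, arbitrary zero padding), via im2col + GEMM.
# ----------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           padding: tuple[int, int]) -> Tensor:
    """2-D cross-correlation over NCHW input; stride 1, zero padding.

    ``weight`` has shape (out_channels, in_channels, kh, kw); with the
    "same" paddings used throughout the network, output spatial size
    equals the input's.
    """
    B, C, H, W = x.data.shape
    O, Ci, kh, kw = weight.data.shape
    if Ci != C:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Ci}")
    ph, pw = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Ho = H + 2 * ph - kh + 1
    Wo = W + 2 * pw - kw + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (B,C,Ho,Wo,kh,kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * Ho * Wo, C * kh * kw)
    wmat = weight.data.reshape(O, C * kh * kw)
    out = cols @ wmat.T
    if bias is not None:
        out += bias.data
    out = out.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    out = np.ascontiguousarray(out)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        go = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, O)
        if bias is not None and bias.requires_grad:
            bias._accumulate(go.sum(axis=0))
        if weight.requires_grad:
            weight._accumulate((go.T @ cols).reshape(O, C, kh, kw))
        if x.requires_grad:
            dcols = (go @ wmat).reshape(B, Ho, Wo, C, kh, kw)
            dxp = np.zeros_like(xp)
            for di in range(kh):
                for dj in range(kw):
                    dxp[:, :, di:di + Ho, dj:dj + Wo] += \
                        dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
            if ph or pw:
                dxp = dxp[:, :, ph:ph + H, pw:pw + W]
            x._accumulate(dxp)

    return Tensor(out, parents=parents, backward=bwd)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Requires even spatial dims."""
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2d requires even spatial dims, got {(H, W)}")
    win = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(B, C, H // 2, W // 2, 4)
    idx = win.argmax(axis=-1)  # first max wins on ties -> deterministic
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        if not x.requires_grad:
            return
        dwin = np.zeros((B, C, H // 2, W // 2, 4), dtype=g.dtype)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = dwin.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(dx.reshape(B, C, H, W))

    return Tensor(out, parents=(x,), backward=bwd)


def _bilinear_matrix(n: int, dtype) -> np.ndarray:
    """Dense (2n, n) interpolation matrix for x2 bilinear upsampling.

    Output sample i sits at source coordinate (i + 0.5)/2 - 0.5 (the
    half-pixel-centre convention); coordinates are clamped at the ends
    so border samples replicate.
    """
    src = np.clip((np.arange(2 * n) + 0.5) / 2.0 - 0.5, 0, n - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n - 1)
    w1 = (src - i0).astype(dtype)
    U = np.zeros((2 * n, n), dtype=dtype)
    U[np.arange(2 * n), i0] += 1.0 - w1
    U[np.arange(2 * n), i1] += w1
    return U


_BILINEAR_CACHE: dict[tuple, np.ndarray] = {}


def _bilinear(n: int, dtype) -> np.ndarray:
    key = (n, np.dtype(dtype).name)
    if key not in _BILINEAR_CACHE:
        _BILINEAR_CACHE[key] = _bilinear_matrix(n, dtype)
    return _BILINEAR_CACHE[key]


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling of an NCHW tensor (half-pixel centres)."""
    B, C, H, W = x.data.shape
    Uh = _bilinear(H, x.data.dtype)
    Uw = _bilinear(W, x.data.dtype)
    x3 = x.data.reshape(B * C, H, W)
    out = (Uh @ x3) @ Uw.T

    def bwd(g):
        if x.requires_grad:
            g3 = g.reshape(B * C, 2 * H, 2 * W)
            x._accumulate(((Uh.T @ g3) @ Uw).reshape(B, C, H, W))

    return Tensor(out.reshape(B, C, 2 * H, 2 * W), parents=(x,), backward=bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """Spatial mean per channel: (B,C,H,W) -> (B,C)."""
    return x.mean(axis=(2, 3))


def global_max_pool(x: Tensor) -> Tensor:
    """Spatial max per channel: (B,C,H,W) -> (B,C,1,1)."""
    B, C, H, W = x.data.shape
    flat = x.data.reshape(B, C, H * W)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)

    def bwd(g):
        if x.requires_grad:
            dflat = np.zeros_like(flat)
            np.put_along_axis(dflat, idx[..., None], g.reshape(B, C, 1), axis=-1)
            x._accumulate(dflat.reshape(B, C, H, W))

    return Tensor(out.reshape(B, C, 1, 1), parents=(x,), backward=bwd)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over an NCHW tensor.

    In training mode the batch statistics normalise and the running
    buffers are updated in place; in evaluation mode the buffers are
    used, making the forward pass deterministic for fixed weights.
    """
    B, C, H, W = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = B * H * W
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        # unbiased estimate in the running buffer, biased in the pass
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gi = gamma.data[None, :, None, None] * inv[None, :, None, None]
        if training:
            n = B * H * W
            gsum = g.sum(axis=(0, 2, 3))[None, :, None, None]
            gxsum = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
            dx = gi * (g - gsum / n - xhat * gxsum / n)
        else:
            dx = gi * g
        x._accumulate(dx.astype(x.data.dtype))

    return Tensor(out.astype(x.data.dtype), parents=(x, gamma, beta), backward=bwd)
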