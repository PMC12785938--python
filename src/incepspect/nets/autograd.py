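"""Minimal reverse-mode autodiff over numpy arrays.

Only the operations needed by the 1-D convolutional regressors live here:
elementwise arithmetic, matmul, reductions, the sigmoid/tanh/softplus/mish
family, fused batch normalization, 1-D convolution (im2col) and max pooling.
Everything runs in float64 on the CPU, which keeps training bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv1d",
    "maxpool1d",
    "adaptive_maxpool1d",
    "batchnorm",
    "no_grad",
]

_GRAD_ENABLED = True

#: Engine dtype. float32 roughly halves step time on memory-bound CPUs and
#: stays bit-reproducible; switch to float64 for finite-difference checks.
DTYPE = np.float32


def set_dtype(dtype) -> None:
    global DTYPE
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be np.float32 or np.float64")
    DTYPE = dtype


@contextmanager
def no_grad():
    """Disable graph construction (inference / validation passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting).
    Returns ``grad`` itself when no reduction is needed."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = requires_grad or (
            _GRAD_ENABLED and any(t.requires_grad for t in _prev)
        )
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev = _prev if self.requires_grad else ()

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray, owned: bool = False) -> None:
        """Add ``g`` to the stored gradient. ``owned=True`` promises ``g`` is
        a fresh array no other node aliases, letting us skip the copy."""
        if self.grad is None:
            self.grad = g if owned else g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    r = _unbroadcast(g, self.data.shape)
                    self._accumulate(r, owned=r is not g)
                if other.requires_grad:
                    r = _unbroadcast(g, other.data.shape)
                    other._accumulate(r, owned=r is not g)

            out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(
                        _unbroadcast(g * other.data, self.data.shape), owned=True
                    )
                if other.requires_grad:
                    other._accumulate(
                        _unbroadcast(g * self.data, other.data.shape), owned=True
                    )

            out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        return self * Tensor._lift(other).pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, _prev=(self,))
        if out.requires_grad:
            def bw(g):
                self._accumulate(
                    g * (exponent * self.data ** (exponent - 1.0)), owned=True
                )

            out._backward = bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        out = Tensor(self.data @ other.data, _prev=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(g @ other.data.T, owned=True)
                if other.requires_grad:
                    other._accumulate(self.data.T @ g, owned=True)

            out._backward = bw
        return out

    __matmul__ = matmul

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))
        if out.requires_grad:
            def bw(g):
                self._accumulate(g * out.data, owned=True)

            out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))
        if out.requires_grad:
            def bw(g):
                self._accumulate(g / self.data, owned=True)

            out._backward = bw
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), _prev=(self,))
        if out.requires_grad:
            def bw(g):
                self._accumulate(g * (1.0 - out.data**2), owned=True)

            out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        # stable: sigma(x) = (1 + tanh(x/2)) / 2
        out = Tensor(0.5 * (1.0 + np.tanh(0.5 * self.data)), _prev=(self,))
        if out.requires_grad:
            def bw(g):
                self._accumulate(g * (out.data * (1.0 - out.data)), owned=True)

            out._backward = bw
        return out

    def softplus(self) -> "Tensor":
        # stable: log(1 + e^x) = max(x, 0) + log1p(e^{-|x|})
        x = self.data
        e = np.exp(-np.abs(x))
        out = Tensor(np.maximum(x, 0.0) + np.log1p(e), _prev=(self,))
        if out.requires_grad:
            def bw(g):
                sig = np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
                self._accumulate(g * sig, owned=True)

            out._backward = bw
        return out

    def mish(self) -> "Tensor":
        """Fused x * tanh(softplus(x))."""
        x = self.data
        e = np.exp(-np.abs(x))
        sp = np.maximum(x, 0.0) + np.log1p(e)
        t = np.tanh(sp)
        out = Tensor(x * t, _prev=(self,))
        if out.requires_grad:
            def bw(g):
                sig = np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
                self._accumulate(g * (t + x * (1.0 - t * t) * sig), owned=True)

            out._backward = bw
        return out

    # -- reductions & shaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))
        if out.requires_grad:
            def bw(g):
                if axis is None:
                    self._accumulate(
                        np.broadcast_to(g, self.data.shape).copy(), owned=True
                    )
                    return
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(
                    np.broadcast_to(g, self.data.shape).copy(), owned=True
                )

            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        idx = np.argmax(self.data, axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out_val = val if keepdims else np.squeeze(val, axis=axis)
        out = Tensor(out_val, _prev=(self,))
        if out.requires_grad:
            def bw(g):
                if not keepdims:
                    g = np.expand_dims(g, axis)
                gx = np.zeros_like(self.data)
                np.put_along_axis(gx, np.expand_dims(idx, axis), g, axis=axis)
                self._accumulate(gx, owned=True)

            out._backward = bw
        return out

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        if out.requires_grad:
            def bw(g):
                self._accumulate(g.reshape(self.data.shape), owned=False)

            out._backward = bw
        return out

    def transpose(self, axes: tuple[int, ...]) -> "Tensor":
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        if out.requires_grad:
            inv = tuple(np.argsort(axes))

            def bw(g):
                self._accumulate(g.transpose(inv), owned=False)

            out._backward = bw
        return out

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accumulate(np.ascontiguousarray(p), owned=True)

        out._backward = bw
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused training-mode batch normalization.

    Normalizes over all axes except the feature axis, which is axis 1 for
    both (N, F) and (N, C, L) inputs. Returns (out, batch_mean, batch_var)
    with the statistics as plain arrays (already detached).
    """
    xd = x.data
    spatial = xd.ndim == 3
    axes = (0, 2) if spatial else (0,)
    shape = (1, -1, 1) if spatial else (1, -1)
    m = xd.shape[0] * (xd.shape[2] if spatial else 1)
    mu = xd.mean(axis=axes, keepdims=True)
    xc = xd - mu
    var = np.mean(xc * xc, axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    gm = gamma.data.reshape(shape)
    out = Tensor(xhat * gm + beta.data.reshape(shape), _prev=(x, gamma, beta))
    if out.requires_grad:
        def bw(g):
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes), owned=True)
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes), owned=True)
            if x.requires_grad:
                dxhat = g * gm
                s1 = dxhat.sum(axis=axes, keepdims=True)
                s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
                x._accumulate(inv / m * (m * dxhat - s1 - xhat * s2), owned=True)

        out._backward = bw
    return out, mu.squeeze(), var.squeeze()


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """1-D cross-correlation. x: (N, C, L), w: (O, C, K), b: (O,)."""
    xd = x.data
    if padding:
        xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding)))
    else:
        xp = xd
    N, C, Lp = xp.shape
    O, Cw, K = w.data.shape
    if Cw != C:
        raise ValueError(f"conv1d channel mismatch: input {C}, weight {Cw}")
    if Lp < K:
        raise ValueError(f"conv1d input length {Lp} (padded) shorter than kernel {K}")
    out_len = (Lp - K) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)[:, :, ::stride, :]
    cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(N, out_len, C * K)
    wmat = w.data.reshape(O, C * K)
    y = cols @ wmat.T  # (N, out_len, O)
    if b is not None:
        y = y + b.data
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(y.transpose(0, 2, 1)), _prev=prev)
    if out.requires_grad:
        def bw(g):
            gt = np.ascontiguousarray(g.transpose(0, 2, 1))  # (N, out_len, O)
            if w.requires_grad:
                gw = gt.reshape(-1, O).T @ cols.reshape(-1, C * K)
                w._accumulate(gw.reshape(O, C, K), owned=True)
            if b is not None and b.requires_grad:
                b._accumulate(gt.sum(axis=(0, 1)), owned=True)
            if x.requires_grad:
                dcols = (gt @ wmat).reshape(N, out_len, C, K).transpose(0, 2, 1, 3)
                dxp = np.zeros((N, C, Lp), dtype=g.dtype)
                for k in range(K):
                    dxp[:, :, k:k + out_len * stride:stride] += dcols[:, :, :, k]
                x._accumulate(
                    dxp[:, :, padding:Lp - padding] if padding else dxp, owned=True
                )

        out._backward = bw
    return out


def maxpool1d(x: Tensor, kernel: int, stride: int | None = None,
              padding: int = 0) -> Tensor:
    """Max pooling along the last axis of (N, C, L)."""
    if stride is None:
        stride = kernel
    xd = x.data
    if padding:
        xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = xd
    N, C, Lp = xp.shape
    out_len = (Lp - kernel) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=2)[:, :, ::stride, :]
    win = np.ascontiguousarray(win)
    idx = np.argmax(win, axis=3)  # (N, C, out_len)
    out = Tensor(np.take_along_axis(win, idx[..., None], axis=3)[..., 0], _prev=(x,))
    if out.requires_grad:
        starts = np.arange(out_len) * stride
        pos = starts[None, None, :] + idx - padding  # position in unpadded input

        def bw(g):
            gx = np.zeros_like(xd)
            nn, cc = np.meshgrid(np.arange(N), np.arange(C), indexing="ij")
            np.add.at(gx, (nn[..., None], cc[..., None], pos), g)
            x._accumulate(gx, owned=True)

        out._backward = bw
    return out


def adaptive_maxpool1d(x: Tensor, output_size: int) -> Tensor:
    """Adaptive max pooling to a fixed output length (window i spans
    [floor(i*L/out), ceil((i+1)*L/out)))."""
    N, C, L = x.data.shape
    if output_size < 1 or output_size > L:
        raise ValueError("output_size must lie in [1, input length]")
    starts = (np.arange(output_size) * L) // output_size
    ends = -(-(np.arange(1, output_size + 1) * L) // output_size)  # ceil
    vals = np.empty((N, C, output_size), dtype=x.data.dtype)
    argpos = np.empty((N, C, output_size), dtype=int)
    for i in range(output_size):
        seg = x.data[:, :, starts[i]:ends[i]]
        a = np.argmax(seg, axis=2)
        argpos[:, :, i] = a + starts[i]
        vals[:, :, i] = np.take_along_axis(seg, a[..., None], axis=2)[..., 0]
    out = Tensor(vals, _prev=(x,))
    if out.requires_grad:
        def bw(g):
            gx = np.zeros_like(x.data)
            nn, cc = np.meshgrid(np.arange(N), np.arange(C), indexing="ij")
            np.add.at(gx, (nn[..., None], cc[..., None], argpos), g)
            x._accumulate(gx, owned=True)

        out._backward = bw
    return out
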