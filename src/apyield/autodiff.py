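"""Minimal reverse-mode automatic differentiation on numpy arrays.

Every learned component in this package (the yield-regression network, the
tabular VAE, the detection blocks) is expressed with :class:`Tensor`
operations; gradients are obtained by one backward sweep over the recorded
operation graph.  The engine is deliberately small: float64 only, CPU only,
dense numpy arrays, and exactly the operations the models need.

Frequency-domain layers use constant DFT matrices (see :func:`dft_matrices`)
so that spectral filtering reduces to real matrix products the engine
already differentiates; at the sequence/image sizes used here this is
numerically identical to an FFT round trip.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = ["Tensor", "concat", "stack", "embedding", "max_pool2d", "softmax",
           "dft_matrices", "idft_matrices"]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (the adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape entry needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic introspection --------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- backward sweep --------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -g * self.data / (other.data ** 2), other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._node(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            a, b = self.data, other.data
            if b.ndim == 1:  # contraction of a's last axis with vector b
                if self.requires_grad:
                    ga = g[..., None] * b if a.ndim > 1 else g * b
                    self._accumulate(_unbroadcast(ga, a.shape))
                if other.requires_grad:
                    gb = np.einsum('...n,...->n', a, g) if a.ndim > 1 else g * a
                    other._accumulate(gb)
            elif a.ndim == 1:  # vector @ matrix
                if self.requires_grad:
                    self._accumulate(np.matmul(b, g) if b.ndim == 2
                                     else np.einsum('...np,...p->n', b, g))
                if other.requires_grad:
                    gb = (np.outer(a, g) if b.ndim == 2
                          else np.einsum('n,...p->...np', a, g))
                    other._accumulate(_unbroadcast(gb, b.shape))
            else:  # both >= 2-D, possibly batched
                if self.requires_grad:
                    ga = np.matmul(g, np.swapaxes(b, -1, -2))
                    self._accumulate(_unbroadcast(ga, a.shape))
                if other.requires_grad:
                    gb = np.matmul(np.swapaxes(a, -1, -2), g)
                    other._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._node(out_data, (self, other), backward)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._node(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data)

        return Tensor._node(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data ** 2))

        return Tensor._node(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._node(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._node(out_data, (self,), backward)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        cdf = 0.5 * (1.0 + erf(self.data / _SQRT2))
        out_data = self.data * cdf

        def backward(g):
            if self.requires_grad:
                pdf = _INV_SQRT_2PI * np.exp(-0.5 * self.data ** 2)
                self._accumulate(g * (cdf + self.data * pdf))

        return Tensor._node(out_data, (self,), backward)

    def clip_min(self, lo: float):
        mask = self.data > lo
        out_data = np.where(mask, self.data, lo)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._node(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * sign)

        return Tensor._node(np.abs(self.data), (self,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis=axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ----------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._node(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._node(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (slice, int)) or p is None or p is Ellipsis
                    for p in parts)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:  # no duplicate positions: plain in-place add
                    full[idx] += g
                else:
                    np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor._node(out_data, (self,), backward)

    def pad(self, pad_width, value: float = 0.0, mode: str = "constant"):
        """Constant or edge padding; `pad_width` as for np.pad."""
        if mode == "constant":
            out_data = np.pad(self.data, pad_width, constant_values=value)
            slices = tuple(slice(lo, lo + n)
                           for (lo, _), n in zip(pad_width, self.data.shape))

            def backward(g):
                if self.requires_grad:
                    self._accumulate(g[slices])
        elif mode == "edge":
            out_data = np.pad(self.data, pad_width, mode="edge")
            idx_map = np.pad(np.arange(self.data.size).reshape(self.data.shape),
                             pad_width, mode="edge")

            def backward(g):
                if self.requires_grad:
                    flat = np.zeros(self.data.size)
                    np.add.at(flat, idx_map.ravel(), g.ravel())
                    self._accumulate(flat.reshape(self.data.shape))
        else:
            raise ValueError(f"unsupported pad mode {mode!r}")

        return Tensor._node(out_data, (self,), backward)


# -- free functions -------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._node(out_data, tensors, backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._node(out_data, tensors, backward)


def embedding(weight: Tensor, idx) -> Tensor:
    """Row lookup `weight[idx]` with scatter-add gradient."""
    idx = np.asarray(idx, dtype=np.int64)
    out_data = weight.data[idx]

    def backward(g):
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, idx, g)
            weight._accumulate(full)

    return Tensor._node(out_data, (weight,), backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shift = t - np.max(t.data, axis=axis, keepdims=True)  # constant shift
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def max_pool2d(x: Tensor, kernel: int, pad: int) -> Tensor:
    """Stride-1 max pooling over the two trailing axes of a 4-D tensor."""
    b, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=-np.inf)
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    flat = win.reshape(b, c, h, w, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gi = np.zeros_like(xp)
        bi, ci, hi, wi = np.indices((b, c, h, w))
        rows = hi + arg // kernel
        cols = wi + arg % kernel
        np.add.at(gi, (bi, ci, rows, cols), g)
        x._accumulate(gi[:, :, pad:pad + h, pad:pad + w])

    return Tensor._node(out_data, (x,), backward)


# -- DFT matrices for spectral layers -------------------------------------

def dft_matrices(n: int):
    """Real/imag parts of the forward DFT matrix for length-n signals.

    ``X = x @ (C + iS)`` equals ``np.fft.fft(x)`` along the last axis.
    """
    k = np.arange(n)
    ang = -2.0 * np.pi * np.outer(k, k) / n
    return np.cos(ang), np.sin(ang)


def idft_matrices(n: int):
    """Inverse-DFT matrices: ``x = Re[(Xr + iXi) @ (C + iS)]`` recovers x."""
    k = np.arange(n)
    ang = 2.0 * np.pi * np.outer(k, k) / n
    return np.cos(ang) / n, np.sin(ang) / n
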