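"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the dose/alpha/beta networks need: broadcast
arithmetic, batched matmul, reductions, elementwise nonlinearities, softmax,
reshape/transpose/slicing/concatenation, patch extraction (``unfold``) for
convolutions and 2x nearest-neighbour upsampling for the decoder. Gradients
are accumulated by topological-order backpropagation from a scalar loss.

All gradients are checked against central finite differences in the test
suite; that check is the correctness contract for this module.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True

#: Working precision of the graph. float32 keeps the memory traffic of
#: training low; the gradient-check tests switch to float64.
DEFAULT_DTYPE = np.float32


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextmanager
def default_dtype(dtype):
    """Temporarily change the dtype newly created tensors use."""
    global DEFAULT_DTYPE
    prev = DEFAULT_DTYPE
    DEFAULT_DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DEFAULT_DTYPE = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_shared")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DEFAULT_DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self._grad_shared = False

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, grad: np.ndarray) -> None:
        # Backward functions never mutate the arrays they hand out, so the
        # first accumulation can alias the incoming buffer; once aliased the
        # tensor must not update that buffer in place.
        raw = np.asarray(grad, dtype=self.data.dtype)
        reduced = _unbroadcast(raw, self.data.shape)
        if self.grad is None:
            self.grad = reduced
            self._grad_shared = reduced is raw
        elif self._grad_shared:
            self.grad = self.grad + reduced
            self._grad_shared = False
        else:
            self.grad += reduced

    # -- op construction helper --------------------------------------------

    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward):
        needs = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=needs)
        if needs:
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self**-1.0

    def __pow__(self, p: float):
        assert np.isscalar(p)

        def bw(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor._make(self.data @ other.data, (self, other), bw)

    # -- elementwise nonlinearities ----------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        def bw(g):
            self._accum(g * (self.data > 0))

        return Tensor._make(np.maximum(self.data, 0.0), (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out_data = np.logaddexp(0.0, self.data)

        def bw(g):
            self._accum(g / (1.0 + np.exp(-self.data)))

        return Tensor._make(out_data, (self,), bw)

    def gelu(self):
        # tanh approximation
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)

        def bw(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            self._accum(g * (0.5 * (1 + t) + 0.5 * x * (1 - t**2) * dinner))

        return Tensor._make(0.5 * x * (1 + t), (self,), bw)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), bw)

    # -- softmax -----------------------------------------------------------

    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def unfold2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    """Extract kernel x kernel patches from images.

    ``x`` has shape (B, H, W, C); the result has shape
    (B, H', W', kernel*kernel*C) with H' = (H + 2p - k)//stride + 1.
    """
    B, H, W, C = x.data.shape
    k, s, p = kernel, stride, padding
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0))) if p else x.data
    Hp, Wp = H + 2 * p, W + 2 * p
    Ho = (Hp - k) // s + 1
    Wo = (Wp - k) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (B, Hp-k+1, Wp-k+1, C, k, k)
    win = win[:, ::s, ::s]
    out_data = win.transpose(0, 1, 2, 4, 5, 3).reshape(B, Ho, Wo, k * k * C)

    def bw(g):
        g = g.reshape(B, Ho, Wo, k, k, C)
        full = np.zeros((B, Hp, Wp, C), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                full[:, i:i + Ho * s:s, j:j + Wo * s:s, :] += g[:, :, :, i, j, :]
        if p:
            full = full[:, p:-p, p:-p, :]
        x._accum(full)

    return Tensor._make(out_data, (x,), bw)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of (B, H, W, C) images."""
    B, H, W, C = x.data.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def bw(g):
        x._accum(g.reshape(B, H, 2, W, 2, C).sum(axis=(2, 4)))

    return Tensor._make(out_data, (x,), bw)
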