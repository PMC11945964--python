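"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based autograd: just the operations the EBUS
classification models need (dense/conv linear algebra, pooling, softmax,
elementwise nonlinearities, reductions, reshapes and concatenation).
Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`
via topological traversal of the recorded graph.
"""

from __future__ import annotations

import contextlib

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the block (inference / frozen paths)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_unbroadcast(grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, out):
            self._accum(-grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_unbroadcast(grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(grad, out):
            self._accum(grad * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), backward)

    # -- matmul ---------------------------------------------------------------
    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(grad, out):
            if self.requires_grad:
                g = grad @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ grad
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(grad, out):
            self._accum(grad * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(grad, out):
            self._accum(grad * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(grad, out):
            self._accum(grad * e)

        return Tensor._make(e, (self,), backward)

    def log(self):
        def backward(grad, out):
            self._accum(grad / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad, out):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = self.data.max(axis=axis, keepdims=True)
        mask = self.data == expanded
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(grad, out):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(mask * (g / counts))

        return Tensor._make(out_data, (self,), backward)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape

        def backward(grad, out):
            self._accum(grad.reshape(old_shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(grad, out):
            self._accum(grad.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    # -- internals ------------------------------------------------------------
    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor (must be scalar if grad omitted)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad, node)


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`, differentiable in every input."""
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad, out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(grad[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis`."""
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, square stride/pad."""
    B, C, H, W = x.data.shape
    O, Ci, kh, kw = weight.data.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]                # B,C,Ho,Wo,kh,kw
    cols = view.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * kh * kw, Ho * Wo)
    wmat = weight.data.reshape(O, C * kh * kw)
    out_data = (wmat @ cols).reshape(B, O, Ho, Wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, O, 1, 1)

    def backward(grad, out):
        gmat = grad.reshape(B, O, Ho * Wo)
        if bias is not None and bias.requires_grad:
            bias._accum(grad.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.einsum("bop,bkp->ok", gmat, cols)
            weight._accum(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gcols = np.einsum("ok,bop->bkp", wmat, gmat)
            gcols = gcols.reshape(B, C, kh, kw, Ho, Wo)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * Ho:stride,
                        j:j + stride * Wo:stride] += gcols[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, parents, backward)


def adaptive_avg_pool2d(x: Tensor, output_size: tuple[int, int]) -> Tensor:
    """Average pooling onto an arbitrary output grid (NCHW).

    Bin *i* of an axis of length H pooled to length oh covers input rows
    [floor(i*H/oh), ceil((i+1)*H/oh)), so uneven sizes are handled and the
    divisible case reduces to block averaging.
    """
    B, C, H, W = x.data.shape
    oh, ow = output_size
    if oh <= 0 or ow <= 0:
        raise ValueError("output size must be positive")
    rb = [(int(np.floor(i * H / oh)), int(np.ceil((i + 1) * H / oh))) for i in range(oh)]
    cb = [(int(np.floor(j * W / ow)), int(np.ceil((j + 1) * W / ow))) for j in range(ow)]
    out_data = np.empty((B, C, oh, ow))
    for i, (r0, r1) in enumerate(rb):
        for j, (c0, c1) in enumerate(cb):
            out_data[:, :, i, j] = x.data[:, :, r0:r1, c0:c1].mean(axis=(2, 3))

    def backward(grad, out):
        gx = np.zeros_like(x.data)
        for i, (r0, r1) in enumerate(rb):
            for j, (c0, c1) in enumerate(cb):
                area = (r1 - r0) * (c1 - c0)
                gx[:, :, r0:r1, c0:c1] += grad[:, :, i:i + 1, j:j + 1] / area
        x._accum(gx)

    return Tensor._make(out_data, (x,), backward)
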