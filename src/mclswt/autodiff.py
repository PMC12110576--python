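"""Tape-based reverse-mode automatic differentiation on NumPy arrays.

A deliberately small engine covering exactly the operations the
sliding-window transformer and its losses need: broadcast arithmetic,
(batched) matrix multiplication, reductions, softmax, GELU, cyclic
rolls, strided sliding-window extraction (for convolution and pooling)
and row gathering (for contrastive pair construction).

Gradients follow NumPy broadcasting semantics; every op's backward pass
is verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "matmul", "concat", "layer_norm"]

_SQRT2 = float(np.sqrt(2.0))
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self._grad_owned = False

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- graph plumbing -------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        # Copy-on-write: borrow the incoming buffer on first contribution
        # (upstream grads are final by reverse-topological order) and
        # allocate only when a second contribution arrives.
        if self.grad is None:
            if grad.dtype != self.data.dtype:
                grad = grad.astype(self.data.dtype)
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):  # scalar fast path: keep dtype
            other = float(other)
            a = self

            def backward_s(g):
                a._accum(g)

            return self._make(a.data + other, (a,), backward_s)
        other = Tensor.as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            other = float(other)
            a = self

            def backward_s(g):
                a._accum(g * other)

            return self._make(a.data * other, (a,), backward_s)
        other = Tensor.as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = Tensor.as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def square(self):
        a = self

        def backward(g):
            a._accum(g * (2.0 * a.data))

        return self._make(a.data * a.data, (a,), backward)

    def sqrt(self, guard: float = 1e-12):
        """Square root; the gradient is guarded near zero."""
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            a._accum(g / (2.0 * np.maximum(out_data, guard)))

        return self._make(out_data, (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return self._make(out_data, (a,), backward)

    def log(self, floor: float | None = None):
        """Natural log; with ``floor`` the argument is clamped below."""
        a = self
        if floor is None:
            arg = a.data
            mask = None
        else:
            arg = np.maximum(a.data, floor)
            mask = a.data > floor

        def backward(g):
            ga = g / arg
            if mask is not None:
                ga = np.where(mask, ga, 0.0)
            a._accum(ga)

        return self._make(np.log(arg), (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(np.where(mask, g, 0.0))

        return self._make(np.where(mask, a.data, 0.0), (a,), backward)

    def gelu(self):
        a = self
        x = a.data
        phi = 0.5 * (1.0 + erf(x * (1.0 / _SQRT2)))

        def backward(g):
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
            a._accum(g * (phi + x * pdf))

        return self._make(x * phi, (a,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                ga = np.broadcast_to(g, a.shape)
            else:
                g_ = g if keepdims else np.expand_dims(g, axis)
                ga = np.broadcast_to(g_, a.shape)
            a._accum(ga)

        return self._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            a._accum((g - (g * s).sum(axis=axis, keepdims=True)) * s)

        return self._make(s, (a,), backward)

    def log_softmax(self, axis: int = -1):
        a = self
        m = a.data.max(axis=axis, keepdims=True)
        z = a.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        s = np.exp(out_data)

        def backward(g):
            a._accum(g - g.sum(axis=axis, keepdims=True) * s)

        return self._make(out_data, (a,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def backward(g):
            a._accum(g.reshape(old))

        return self._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), backward)

    def roll(self, shift: int, axis: int):
        a = self

        def backward(g):
            a._accum(np.roll(g, -shift, axis=axis))

        return self._make(np.roll(a.data, shift, axis=axis), (a,), backward)

    def unfold(self, axis: int, size: int, step: int):
        """Extract sliding windows along ``axis``.

        Input shape ``(..., L, ...)`` becomes ``(..., n_win, size, ...)``
        with ``n_win = (L - size)//step + 1``; windows start every
        ``step`` samples. Used for valid convolution (step=1) and
        average pooling (step=stride).
        """
        a = self
        axis = axis % a.ndim
        L = a.shape[axis]
        n_win = (L - size) // step + 1
        view = np.lib.stride_tricks.sliding_window_view(a.data, size, axis=axis)
        # view: (..., L-size+1, ..., size) with window dim appended last
        idx = [slice(None)] * view.ndim
        idx[axis] = slice(0, step * n_win, step)
        win = np.moveaxis(view[tuple(idx)], -1, axis + 1).copy()

        def backward(g):
            ga = np.zeros_like(a.data)
            sl = [slice(None)] * ga.ndim
            gl = [slice(None)] * g.ndim
            for i in range(size):
                sl[axis] = slice(i, i + step * n_win, step)
                gl[axis + 1] = i
                ga[tuple(sl)] += g[tuple(gl)]
            a._accum(ga)

        return self._make(win, (a,), backward)

    def take(self, indices, axis: int = 0):
        """Gather slices along ``axis`` (rows by default)."""
        a = self
        indices = np.asarray(indices)

        def backward(g):
            ga = np.zeros_like(a.data)
            if axis == 0:
                np.add.at(ga, indices, g)
            else:
                ga_m = np.moveaxis(ga, axis, 0)
                np.add.at(ga_m, indices, np.moveaxis(g, axis, 0))
            a._accum(ga)

        return self._make(np.take(a.data, indices, axis=axis), (a,), backward)

    def __matmul__(self, other):
        return matmul(self, other)


def matmul(a: Tensor, b: Tensor, counter: list | None = None) -> Tensor:
    """(Batched) matrix product following ``np.matmul`` broadcasting.

    ``counter``, if given, is a one-element list accumulating the
    multiply–accumulate count of the product (used by the attention
    complexity measurements).
    """
    a = Tensor.as_tensor(a)
    b = Tensor.as_tensor(b)
    out_data = np.matmul(a.data, b.data)
    if counter is not None:
        batch = int(np.prod(out_data.shape[:-2])) if out_data.ndim > 2 else 1
        m, n = out_data.shape[-2], out_data.shape[-1]
        k = a.data.shape[-1]
        counter[0] += batch * m * n * k

    def backward(g):
        if not g.flags.c_contiguous:  # BLAS degrades badly on strided views
            g = np.ascontiguousarray(g)
        if a.requires_grad:
            bt = np.swapaxes(b.data, -1, -2) if b.data.ndim >= 2 else b.data
            ga = np.matmul(g, bt)
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            at = np.swapaxes(a.data, -1, -2) if a.data.ndim >= 2 else a.data
            gb = np.matmul(at, g)
            b._accum(_unbroadcast(gb, b.shape))

    return a._make(out_data, (a, b), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis: gamma * z + beta.

    Single op with the closed-form backward (cheaper than composing it
    from primitives; verified against the composed version in tests).
    """
    x = Tensor.as_tensor(x)
    gamma = Tensor.as_tensor(gamma)
    beta = Tensor.as_tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = xc * inv

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * y).reshape(-1, y.shape[-1]).sum(axis=0))
        if beta.requires_grad:
            beta._accum(g.reshape(-1, y.shape[-1]).sum(axis=0))
        if x.requires_grad:
            dy = g * gamma.data
            dx = inv * (
                dy - dy.mean(axis=-1, keepdims=True)
                - y * (dy * y).mean(axis=-1, keepdims=True)
            )
            x._accum(dx)

    out = Tensor(y * gamma.data + beta.data)
    out.requires_grad = x.requires_grad or gamma.requires_grad or beta.requires_grad
    if out.requires_grad:
        out._parents = (x, gamma, beta)
        out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(gpart)

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out
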