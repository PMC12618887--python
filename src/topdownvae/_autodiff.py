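"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based engine sufficient for the ELBO objectives in this package:
dense layers with softplus activations, Gaussian/Laplace reparameterized
sampling, closed-form KL terms, and reductions.  Broadcasting follows numpy
semantics; gradients of broadcast operands are summed back to the operand
shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softplus", "grad_check", "default_dtype"]

# module-level default dtype for newly created tensors; float32 roughly
# halves training wall-clock on CPU at ample precision for SGD
DEFAULT_DTYPE = np.float64


class default_dtype:
    """Context manager temporarily switching the tensor dtype."""

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype)

    def __enter__(self):
        global DEFAULT_DTYPE
        self._old = DEFAULT_DTYPE
        DEFAULT_DTYPE = self.dtype
        return self

    def __exit__(self, *exc):
        global DEFAULT_DTYPE
        DEFAULT_DTYPE = self._old
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 stretched by broadcasting
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DEFAULT_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor._from_op(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor._from_op(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor._from_op(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data
        return Tensor._from_op(
            a @ b,
            (self, other),
            lambda g: (g @ b.T, a.T @ g),
        )

    def __pow__(self, p: float):
        return Tensor._from_op(
            self.data**p, (self,), lambda g: (g * p * self.data ** (p - 1),)
        )

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def abs(self):
        return Tensor._from_op(
            np.abs(self.data), (self,), lambda g: (g * np.sign(self.data),)
        )

    def softplus(self):
        # numerically stable log(1 + e^x) with one exp evaluation
        x = self.data
        e = np.exp(-np.abs(x))
        out_data = np.maximum(x, 0.0) + np.log1p(e)
        sig = np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
        return Tensor._from_op(out_data, (self,), lambda g: (g * sig,))

    # -- reductions and shaping -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        return Tensor._from_op(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(self.shape),)
        )

    # -- backward pass --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        grads: dict[int, np.ndarray] = {
            id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g
        # leaves collect remaining grads
        for node in topo:
            g = grads.pop(id(node), None)
            if g is not None:
                node.grad = g if node.grad is None else node.grad + g

    def zero_grad(self):
        self.grad = None


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(data, tuple(tensors), backward)


def softplus(x: Tensor) -> Tensor:
    return x.softplus()


def grad_check(fn, params, eps: float = 1e-6):
    """Max relative error between analytic and central-difference gradients.

    `fn` maps the list of parameter Tensors to a scalar Tensor.
    """
    out = fn(params)
    for p in params:
        p.zero_grad()
    out = fn(params)
    out.backward()
    worst = 0.0
    for p in params:
        analytic = p.grad if p.grad is not None else np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p.data[idx]
            p.data[idx] = orig + eps
            fp = float(fn(params).data)
            p.data[idx] = orig - eps
            fm = float(fn(params).data)
            p.data[idx] = orig
            numeric = (fp - fm) / (2 * eps)
            denom = max(1.0, abs(numeric), abs(analytic[idx]))
            worst = max(worst, abs(numeric - analytic[idx]) / denom)
    return worst
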