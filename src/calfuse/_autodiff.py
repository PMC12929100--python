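"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the cross-modal encoder needs: broadcasted
elementwise arithmetic, (batched) matrix products, tanh/relu/exp/log,
axis reductions, shape manipulation and a numerically stable softmax /
log-softmax built from those primitives. Everything is float64.

Gradients of every primitive are checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "softmax", "log_softmax", "layer_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad = None
        self._parents = _parents
        self._vjp = _vjp  # callable(out_grad) -> tuple of parent grads (or None)

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

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other),
                     _vjp=lambda g: (_unbroadcast(g, self.shape),
                                     _unbroadcast(g, other.shape)))
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other),
                     _vjp=lambda g: (_unbroadcast(g * other.data, self.shape),
                                     _unbroadcast(g * self.data, other.shape)))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other),
                     _vjp=lambda g: (_unbroadcast(g / other.data, self.shape),
                                     _unbroadcast(-g * self.data / other.data ** 2,
                                                  other.shape)))
        return out

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out = Tensor(self.data ** p, _parents=(self,),
                     _vjp=lambda g: (g * p * self.data ** (p - 1),))
        return out

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data

        def vjp(g):
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return Tensor(a @ b, _parents=(self, other), _vjp=vjp)

    # -- nonlinearities -------------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        return Tensor(y, _parents=(self,), _vjp=lambda g: (g * (1.0 - y ** 2),))

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, _parents=(self,), _vjp=lambda g: (g * mask,))

    def exp(self):
        y = np.exp(self.data)
        return Tensor(y, _parents=(self,), _vjp=lambda g: (g * y,))

    def log(self):
        return Tensor(np.log(self.data), _parents=(self,),
                      _vjp=lambda g: (g / self.data,))

    # -- reductions & shapes --------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor(out_data, _parents=(self,), _vjp=vjp)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.shape
        return Tensor(self.data.reshape(*shape), _parents=(self,),
                      _vjp=lambda g: (g.reshape(old),))

    def swapaxes(self, a, b):
        return Tensor(np.swapaxes(self.data, a, b), _parents=(self,),
                      _vjp=lambda g: (np.swapaxes(g, a, b),))

    def max(self, axis=None, keepdims=False):
        """Max reduction treated as piecewise-constant selection."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data)
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def vjp(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (mask * g,)

        data = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return Tensor(data, _parents=(self,), _vjp=vjp)

    # -- backward pass --------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS post-order
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

        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


# -- composite ops -------------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max shift is detached (zero gradient)."""
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis, then apply an affine gain/bias."""
    mu = x.mean(axis=-1, keepdims=True)
    centred = x - mu
    var = (centred ** 2).mean(axis=-1, keepdims=True)
    return centred / (var + eps) ** 0.5 * gain + bias
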