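"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express and train the package's classifier
architectures (dense, 1-D convolution via gather+matmul, max pooling, LSTM,
additive attention) with exact gradients. Float64 throughout; everything is
deterministic given the caller's RNG. Gradient correctness is verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "add", "sub", "mul", "div", "neg", "matmul",
    "relu", "sigmoid", "tanh", "exp", "log",
    "tsum", "tmax", "reshape", "take", "narrow", "softmax",
    "Adam",
]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor into the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order topological sort
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g


def constant(data) -> Tensor:
    return Tensor(data)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *g* down to *shape*, undoing numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g.reshape(shape)


def _binary(a: Tensor, b: Tensor, out_data, grad_a, grad_b) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad_a(g), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(grad_b(g), b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def sub(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data - b.data, lambda g: g, lambda g: -g)


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data * b.data,
                   lambda g: g * b.data, lambda g: g * a.data)


def div(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data / b.data,
                   lambda g: g / b.data,
                   lambda g: -g * a.data / (b.data ** 2))


def neg(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(-g)

    return Tensor(-a.data, parents=(a,), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; *b* must be 2-D, *a* may carry leading batch axes."""
    if b.data.ndim != 2:
        raise ValueError("matmul rhs must be 2-D")
    out = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            axes = tuple(range(a.data.ndim - 1))
            b._accumulate(np.tensordot(a.data, g, axes=(axes, axes)))

    return Tensor(out, parents=(a, b), backward=backward)


def _unary(a: Tensor, out_data, grad_fn) -> Tensor:
    def backward(g):
        a._accumulate(grad_fn(g))

    return Tensor(out_data, parents=(a,), backward=backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return _unary(a, a.data * mask, lambda g: g * mask)


def sigmoid(a: Tensor) -> Tensor:
    with np.errstate(over="ignore"):  # saturates cleanly to 0/1
        out = 1.0 / (1.0 + np.exp(-a.data))
    return _unary(a, out, lambda g: g * out * (1.0 - out))


def tanh(a: Tensor) -> Tensor:
    out = np.tanh(a.data)
    return _unary(a, out, lambda g: g * (1.0 - out ** 2))


def exp(a: Tensor) -> Tensor:
    out = np.exp(a.data)
    return _unary(a, out, lambda g: g * out)


def log(a: Tensor) -> Tensor:
    return _unary(a, np.log(a.data), lambda g: g / a.data)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return Tensor(out, parents=(a,), backward=backward)


def tmax(a: Tensor, axis: int) -> Tensor:
    """Max over *axis*; gradient flows to the first maximum (deterministic)."""
    idx = np.argmax(a.data, axis=axis)
    out = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)

    def backward(g):
        if g.ndim == a.data.ndim - 1:
            g = np.expand_dims(g, axis)
        buf = np.zeros_like(a.data)
        np.put_along_axis(buf, np.expand_dims(idx, axis), g, axis=axis)
        a._accumulate(buf)

    return Tensor(np.squeeze(out, axis=axis), parents=(a,), backward=backward)


def reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return Tensor(a.data.reshape(shape), parents=(a,), backward=backward)


def take(a: Tensor, indices: np.ndarray, axis: int = 0) -> Tensor:
    """Gather along *axis* with an integer index array (embedding lookup,
    window extraction). Backward scatter-adds."""
    indices = np.asarray(indices)
    out = np.take(a.data, indices, axis=axis)

    def backward(g):
        buf = np.zeros_like(a.data)
        buf_moved = np.moveaxis(buf, axis, 0)
        g_moved = np.moveaxis(
            g, tuple(range(axis, axis + indices.ndim)), tuple(range(indices.ndim))
        )
        np.add.at(buf_moved, indices, g_moved)
        a._accumulate(buf)

    return Tensor(out, parents=(a,), backward=backward)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice [start, start+length) along *axis*."""
    slicer = [slice(None)] * a.data.ndim
    slicer[axis] = slice(start, start + length)
    slicer = tuple(slicer)

    def backward(g):
        buf = np.zeros_like(a.data)
        buf[slicer] = g
        a._accumulate(buf)

    return Tensor(a.data[slicer], parents=(a,), backward=backward)


def softmax(a: Tensor, axis: int) -> Tensor:
    shifted = sub(a, constant(a.data.max(axis=axis, keepdims=True)))
    e = exp(shifted)
    return div(e, tsum(e, axis=axis, keepdims=True))


class Adam:
    """Adam optimizer over a dict of named parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self._t += 1
        for name, p in self.params.items():
            if p.grad is None:
                continue
            m = self._m[name] = self.beta1 * self._m[name] + (1 - self.beta1) * p.grad
            v = self._v[name] = self.beta2 * self._v[name] + (1 - self.beta2) * p.grad ** 2
            m_hat = m / (1 - self.beta1 ** self._t)
            v_hat = v / (1 - self.beta2 ** self._t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
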