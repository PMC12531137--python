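"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model's trainable components (hierarchical attention, hypergraph
convolution, projection heads, gating and inter-view attention, decoder)
are expressed as compositions of the primitives defined here; gradients
are obtained by reverse-mode accumulation through the recorded graph.
The op set is deliberately small: elementwise arithmetic with numpy
broadcasting, matmul, transpose, concatenate, exp/log/sqrt, and the
activations the model uses (ReLU, ELU, sigmoid).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "glorot_uniform", "Adam", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:  # inner product
                ga, gb = g * b, g * a
            elif a.ndim == 1:  # (k,) @ (k,m) -> (m,)
                ga, gb = b @ g, np.outer(a, g)
            elif b.ndim == 1:  # (n,k) @ (k,) -> (n,)
                ga, gb = np.outer(g, b), a.T @ g
            else:
                ga, gb = g @ b.T, a.T @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    # -- shape ---------------------------------------------------------
    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = backward
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, parents=(self,))
        out._backward = lambda g: (g.T,)
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: (g * out.data,)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self) -> "Tensor":
        out = Tensor(np.sqrt(self.data), parents=(self,))
        out._backward = lambda g: (g * 0.5 / out.data,)
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: (g * (self.data > 0.0),)
        return out

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0.0
        val = np.where(pos, self.data, alpha * np.expm1(self.data))
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: (g * np.where(pos, 1.0, val + alpha),)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    # -- autodiff ------------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of a scalar output into every ancestor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep at many epochs
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

        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad:
                        continue
                    acc = grads.get(id(parent))
                    grads[id(parent)] = pg if acc is None else acc + pg
            else:
                node.grad = g if node.grad is None else node.grad + g


def concat(tensors, axis: int = 0) -> Tensor:
    """Differentiable concatenation along `axis`."""
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = backward
    return out


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    """Glorot/Xavier-uniform initialized trainable matrix."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)), requires_grad=True)


class Adam:
    """Adam optimizer over a flat list of trainable tensors."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
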