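"""Reverse-mode automatic differentiation on NumPy arrays.

This is the package's compute core: a small define-by-run tape with the
handful of operations the chemogenomic models need (dense affine maps,
sparse neighbourhood aggregation via matmul, strided 1D convolution,
elementwise nonlinearities, sum reductions, concatenation, and a
numerically stable binary cross-entropy on logits with an optional
mask).  Everything is float64 and single-threaded, so training is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "add",
    "mul",
    "matmul",
    "sigmoid",
    "relu",
    "identity",
    "tensor_sum",
    "concat",
    "conv1d",
    "bce_with_logits",
    "Adam",
    "ACTIVATIONS",
]


class Tensor:
    """Node of the autodiff graph.

    ``_backward`` maps the gradient w.r.t. this node to a tuple of
    gradients aligned with ``parents``.
    """

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable] = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self.parents)
        self.grad: Optional[np.ndarray] = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self, grad=None) -> None:
        """Accumulate gradients into every reachable parameter."""
        if grad is None:
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
            for p in node.parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node.parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
        # a root that is itself a leaf parameter
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data

    def backward(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return Tensor(out, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data @ b.data

    def backward(g):
        return g @ b.data.T, a.data.T @ g

    return Tensor(out, (a, b), backward)


def sigmoid(x) -> Tensor:
    x = _as_tensor(x)
    # stable in both tails
    out = np.empty_like(x.data)
    pos = x.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    out[~pos] = ex / (1.0 + ex)

    def backward(g):
        return (g * out * (1.0 - out),)

    return Tensor(out, (x,), backward)


def relu(x) -> Tensor:
    x = _as_tensor(x)
    out = np.maximum(x.data, 0.0)

    def backward(g):
        return (g * (x.data > 0.0),)

    return Tensor(out, (x,), backward)


def identity(x) -> Tensor:
    return _as_tensor(x)


ACTIVATIONS: dict[str, Callable[[Tensor], Tensor]] = {
    "sigmoid": sigmoid,
    "relu": relu,
    "identity": identity,
}


def tensor_sum(x, axis=None, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, x.data.shape).copy(),)

    return Tensor(out, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, tuple(tensors), backward)


def conv1d(x, weight, bias, stride: int, padding: str) -> Tensor:
    """Strided cross-correlation along the sequence axis.

    x: (L, C_in); weight: (C_out, k, C_in); bias: (C_out,).
    ``same_zero`` zero-pads so the output has ceil(L / stride)
    positions; ``valid`` yields floor((L - k) / stride) + 1 and
    requires L >= k.
    """
    x, weight, bias = _as_tensor(x), _as_tensor(weight), _as_tensor(bias)
    length, c_in = x.data.shape
    c_out, k, c_in_w = weight.data.shape
    if c_in != c_in_w:
        raise ValueError(f"input has {c_in} channels, filters expect {c_in_w}")
    if stride < 1 or k < 1:
        raise ValueError("stride and filter size must be >= 1")
    if padding == "same_zero":
        out_len = -(-length // stride)  # ceil
        total_pad = max((out_len - 1) * stride + k - length, 0)
        left = total_pad // 2
        right = total_pad - left
    elif padding == "valid":
        if length < k:
            raise ValueError(
                f"sequence length {length} shorter than filter size {k} under valid padding"
            )
        out_len = (length - k) // stride + 1
        left = right = 0
    else:
        raise ValueError(f"unknown padding policy {padding!r}")
    xp = np.pad(x.data, ((left, right), (0, 0)))
    idx = np.arange(out_len)[:, None] * stride + np.arange(k)[None, :]
    patches = xp[idx]  # (out_len, k, C_in)
    out = np.tensordot(patches, weight.data, axes=([1, 2], [1, 2])) + bias.data

    def backward(g):
        gw = np.tensordot(g, patches, axes=([0], [0]))  # (C_out, k, C_in)
        gb = g.sum(axis=0)
        gpatches = np.tensordot(g, weight.data, axes=([1], [0]))  # (out_len, k, C_in)
        gxp = np.zeros_like(xp)
        np.add.at(gxp, idx, gpatches)
        gx = gxp[left : left + length]
        return gx, gw, gb

    return Tensor(out, (x, weight, bias), backward)


def bce_with_logits(logits, targets, mask=None, reduction: str = "mean") -> Tensor:
    """Binary cross-entropy on logits, numerically stable.

    ``mask`` (same shape, 0/1) zeroes both the loss and the gradient of
    masked entries — the convention for unknown labels in partially
    observed multi-task matrices.
    """
    logits = _as_tensor(logits)
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    m = np.ones_like(per) if mask is None else np.asarray(mask, dtype=np.float64)
    per = per * m
    if reduction == "mean":
        denom = max(m.sum(), 1.0)
    elif reduction == "sum":
        denom = 1.0
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    out = per.sum() / denom

    def backward(g):
        p = np.empty_like(z)
        pos = z >= 0
        p[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        p[~pos] = ez / (1.0 + ez)
        return (g * m * (p - y) / denom,)

    return Tensor(out, (logits,), backward)


class Adam:
    """Adam optimizer with decoupled-free (classic L2) weight decay."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
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
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    """Glorot/Xavier uniform initialisation."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)
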