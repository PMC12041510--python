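"""Minimal reverse-mode autodiff on NumPy arrays.

This module is the numerical core the forecaster is built on: a ``Tensor``
wrapping a float64 ndarray, a small set of differentiable operations (dense
layers, LSTM cell, softmax, layer normalisation, dropout, elementwise
nonlinearities) and an Adam optimiser.  Gradients are accumulated by a
topological backward sweep.  Everything is deliberately float64 and
single-threaded so runs are bit-reproducible under a fixed seed.

The op set is exactly what a temporal fusion transformer needs -- nothing
more.  Fused ops (``lstm_cell``, ``layer_norm``, ``softmax``) keep the graph
small, which matters because the per-timestep recurrence is a Python loop.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "param",
    "const",
    "add",
    "sub",
    "mul",
    "matmul",
    "linear",
    "concat",
    "slice_axis",
    "reshape",
    "transpose",
    "sigmoid",
    "tanh",
    "elu",
    "relu",
    "softmax",
    "layer_norm",
    "dropout",
    "embedding",
    "lstm_cell",
    "sum_",
    "mean_",
    "scale",
    "add_const",
    "mul_const",
    "Adam",
    "grad_check",
]


class Tensor:
    """A node in the computation graph.

    ``data`` is always a float64 ndarray.  ``grad`` is filled during
    :meth:`backward`.  Leaf tensors created with ``requires_grad=True`` are
    trainable parameters; everything else only carries gradients through.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def param(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def const(data) -> Tensor:
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _binary(a: Tensor, b: Tensor, out: np.ndarray, da, db) -> Tensor:
    def backward(g: np.ndarray) -> None:
        a._accumulate(_unbroadcast(da(g), a.data.shape))
        b._accumulate(_unbroadcast(db(g), b.data.shape))

    return Tensor(out, parents=(a, b), backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def sub(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data - b.data, lambda g: g, lambda g: -g)


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data * b.data, lambda g: g * b.data, lambda g: g * a.data)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data

    def backward(g: np.ndarray) -> None:
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor(out, parents=(a, b), backward=backward)


def linear(x: Tensor, W: Tensor, b: Tensor | None = None) -> Tensor:
    """x @ W + b with a fused backward (x: (..., in), W: (in, out))."""
    out = x.data @ W.data
    if b is not None:
        out = out + b.data
    parents = (x, W) if b is None else (x, W, b)

    def backward(g: np.ndarray) -> None:
        x._accumulate(g @ W.data.T)
        gW = x.data.reshape(-1, x.data.shape[-1]).T @ g.reshape(-1, g.shape[-1])
        W._accumulate(gW)
        if b is not None:
            b._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))

    return Tensor(out, parents=parents, backward=backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return Tensor(out, parents=tuple(tensors), backward=backward)


def slice_axis(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    idx = [slice(None)] * x.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out = x.data[idx]

    def backward(g: np.ndarray) -> None:
        full = np.zeros_like(x.data)
        full[idx] = g
        x._accumulate(full)

    return Tensor(out, parents=(x,), backward=backward)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    out = x.data.reshape(shape)

    def backward(g: np.ndarray) -> None:
        x._accumulate(g.reshape(x.data.shape))

    return Tensor(out, parents=(x,), backward=backward)


def transpose(x: Tensor, axes: tuple[int, ...]) -> Tensor:
    out = x.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g: np.ndarray) -> None:
        x._accumulate(g.transpose(inv))

    return Tensor(out, parents=(x,), backward=backward)


def _unary(x: Tensor, out: np.ndarray, dx) -> Tensor:
    def backward(g: np.ndarray) -> None:
        x._accumulate(dx(g))

    return Tensor(out, parents=(x,), backward=backward)


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


def sigmoid(x: Tensor) -> Tensor:
    s = _stable_sigmoid(x.data)
    return _unary(x, s, lambda g: g * s * (1.0 - s))


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    return _unary(x, t, lambda g: g * (1.0 - t * t))


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    neg = alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0)
    out = np.where(x.data > 0, x.data, neg)
    return _unary(x, out, lambda g: g * np.where(x.data > 0, 1.0, neg + alpha))


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)
    return _unary(x, out, lambda g: g * (x.data > 0))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g: np.ndarray) -> None:
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    return Tensor(s, parents=(x,), backward=backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis; gamma/beta shaped (d,)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = gamma.data * xhat + beta.data
    d = x.data.shape[-1]

    def backward(g: np.ndarray) -> None:
        gxhat = g * gamma.data
        gx = inv * (
            gxhat
            - gxhat.mean(axis=-1, keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True)
        )
        x._accumulate(gx)
        gamma._accumulate((g * xhat).reshape(-1, d).sum(axis=0))
        beta._accumulate(g.reshape(-1, d).sum(axis=0))

    return Tensor(out, parents=(x, gamma, beta), backward=backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = rng.random(x.data.shape) >= p
    scale_ = 1.0 / (1.0 - p)
    out = x.data * keep * scale_
    return _unary(x, out, lambda g: g * keep * scale_)


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather: weight (n_rows, d), idx integer array (...,) -> (..., d)."""
    idx = np.asarray(idx, dtype=np.intp)
    out = weight.data[idx]

    def backward(g: np.ndarray) -> None:
        gw = np.zeros_like(weight.data)
        np.add.at(gw, idx.reshape(-1), g.reshape(-1, weight.data.shape[-1]))
        weight._accumulate(gw)

    return Tensor(out, parents=(weight,), backward=backward)


def lstm_cell(
    x: Tensor, h: Tensor, c: Tensor, Wx: Tensor, Wh: Tensor, b: Tensor
) -> tuple[Tensor, Tensor]:
    """One fused LSTM step.

    x: (B, d_in); h, c: (B, d); Wx: (d_in, 4d); Wh: (d, 4d); b: (4d,).
    Gate order i, f, g, o.  Returns (h_new, c_new) sharing a fused backward.
    """
    d = h.data.shape[-1]
    gates = x.data @ Wx.data + h.data @ Wh.data + b.data
    i = _stable_sigmoid(gates[:, :d])
    f = _stable_sigmoid(gates[:, d : 2 * d])
    g_ = np.tanh(gates[:, 2 * d : 3 * d])
    o = _stable_sigmoid(gates[:, 3 * d :])
    c_new = f * c.data + i * g_
    tanh_c = np.tanh(c_new)
    h_new = o * tanh_c

    parents = (x, h, c, Wx, Wh, b)
    # c_out carries no backward of its own: its accumulated grad is consumed
    # by h_out's fused backward.  Ordering is safe because every downstream
    # consumer of c_out (the next timestep's cell, or the loss) also consumes
    # h state derived from h_out, so in the reverse topological sweep all
    # contributions to c_out.grad land before h_out's backward fires.
    c_out = Tensor(c_new, parents=parents, backward=None)

    def backward_h(gh: np.ndarray) -> None:
        gc = c_out.grad if c_out.grad is not None else 0.0
        go = gh * tanh_c
        gc_total = gc + gh * o * (1.0 - tanh_c * tanh_c)
        gi = gc_total * g_
        gf = gc_total * c.data
        gg = gc_total * i
        d_gates = np.concatenate(
            [
                gi * i * (1.0 - i),
                gf * f * (1.0 - f),
                gg * (1.0 - g_ * g_),
                go * o * (1.0 - o),
            ],
            axis=1,
        )
        x._accumulate(d_gates @ Wx.data.T)
        h._accumulate(d_gates @ Wh.data.T)
        c._accumulate(gc_total * f)
        Wx._accumulate(x.data.T @ d_gates)
        Wh._accumulate(h.data.T @ d_gates)
        b._accumulate(d_gates.sum(axis=0))

    h_out = Tensor(h_new, parents=parents + (c_out,), backward=backward_h)
    return h_out, c_out


def sum_(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g: np.ndarray) -> None:
        if axis is None:
            x._accumulate(np.broadcast_to(g, x.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.data.shape).copy())

    return Tensor(out, parents=(x,), backward=backward)


def mean_(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = x.data.size if axis is None else x.data.shape[axis]
    s = sum_(x, axis=axis, keepdims=keepdims)
    return scale(s, 1.0 / n)


def scale(x: Tensor, k: float) -> Tensor:
    return _unary(x, x.data * k, lambda g: g * k)


def add_const(x: Tensor, c) -> Tensor:
    return _unary(x, x.data + np.asarray(c, dtype=np.float64), lambda g: g)


def mul_const(x: Tensor, c) -> Tensor:
    carr = np.asarray(c, dtype=np.float64)
    return _unary(x, x.data * carr, lambda g: g * carr)


class Adam:
    """Adam with optional global gradient-norm clipping."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float | None = None,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm and total > 0:
                k = self.clip_norm / total
                grads = [g * k for g in grads]
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def grad_check(
    f: Callable[[list[Tensor]], Tensor],
    params: list[Tensor],
    eps: float = 1e-6,
) -> float:
    """Max relative error between analytic and central-difference gradients."""
    loss = f(params)
    for p in params:
        p.grad = None
    loss.backward()
    worst = 0.0
    for p in params:
        analytic = p.grad if p.grad is not None else np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        while not it.finished:
            ix = it.multi_index
            orig = p.data[ix]
            p.data[ix] = orig + eps
            hi = f(params).item()
            p.data[ix] = orig - eps
            lo = f(params).item()
            p.data[ix] = orig
            num = (hi - lo) / (2 * eps)
            denom = max(1.0, abs(num), abs(analytic[ix]))
            worst = max(worst, abs(num - analytic[ix]) / denom)
            it.iternext()
    return worst
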