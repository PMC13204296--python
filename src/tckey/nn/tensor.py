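"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: enough primitives to express causal dilated
convolutions, batch/layer normalization, multi-head attention, and
cross-entropy training, with exact float64 arithmetic so unit tests can
compare against hand-rolled oracles at tight tolerances.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "causal_conv1d", "softmax", "log_softmax", "cross_entropy"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the shape of its source operand."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array/scalar, got Tensor")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = _backward
        self._prev = _prev
        self.name: str | None = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def _binary(self, other, fwd, bwd):
        other_t = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        out_data = fwd(self.data, other_t.data)
        req = self.requires_grad or other_t.requires_grad
        out = Tensor(out_data, requires_grad=req, _prev=(self, other_t))

        def _backward(g):
            ga, gb = bwd(g, self.data, other_t.data)
            if self.requires_grad:
                self._accumulate(_sum_to_shape(ga, self.data.shape))
            if other_t.requires_grad:
                other_t._accumulate(_sum_to_shape(gb, other_t.data.shape))

        out._backward = _backward if req else None
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return self._binary(other, lambda a, b: b - a, lambda g, a, b: (-g, g))

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b, lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(
            other,
            lambda a, b: a / b,
            lambda g, a, b: (g / b, -g * a / (b * b)),
        )

    def __rtruediv__(self, other):
        return self._binary(
            other,
            lambda a, b: b / a,
            lambda g, a, b: (-g * b / (a * a), g / a),
        )

    def __neg__(self):
        out = Tensor(-self.data, requires_grad=self.requires_grad, _prev=(self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __pow__(self, p: float):
        pd = float(p)
        out = Tensor(self.data**pd, requires_grad=self.requires_grad, _prev=(self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g * pd * self.data ** (pd - 1.0))
        return out

    def __matmul__(self, other):
        def bwd(g, a, b):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return ga, gb

        return self._binary(other, lambda a, b: a @ b, bwd)

    # ------------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)
        out = Tensor(out_data, requires_grad=self.requires_grad, _prev=(self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g * out_data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, _prev=(self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, requires_grad=self.requires_grad, _prev=(self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, requires_grad=self.requires_grad, _prev=(self,))
        if self.requires_grad:
            shape = self.data.shape

            def _backward(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, shape).copy())
                    return
                gg = g
                if not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    for ax in sorted(a % len(shape) for a in axes):
                        gg = np.expand_dims(gg, ax)
                self._accumulate(np.broadcast_to(gg, shape).copy())

            out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.data.shape
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad, _prev=(self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(src_shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad, _prev=(self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), requires_grad=self.requires_grad, _prev=(self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(np.swapaxes(g, a, b))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], requires_grad=self.requires_grad, _prev=(self,))
        if self.requires_grad:
            advanced = _has_advanced_index(key)

            def _backward(g):
                gx = np.zeros_like(self.data)
                if advanced:
                    np.add.at(gx, key, g)
                else:
                    gx[key] += g
                self._accumulate(gx)

            out._backward = _backward
        return out


def _has_advanced_index(key) -> bool:
    parts = key if isinstance(key, tuple) else (key,)
    return any(isinstance(p, (list, np.ndarray)) for p in parts)


# ---------------------------------------------------------------------- fused
def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``."""
    labels = np.asarray(labels)
    n = logits.shape[0]
    lsm = log_softmax(logits, axis=-1)
    picked = lsm[np.arange(n), labels]
    return -picked.mean()


def causal_conv1d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    dilation: int = 1,
    stride: int = 1,
) -> Tensor:
    """Left-padded causal 1-D convolution.

    ``y[b, o, t] = sum_{c,i} weight[o, c, i] * x[b, c, t*stride - dilation*i]``
    with zeros for negative indices, so each output depends only on current
    and past inputs.  Output length is ``ceil(T / stride)``.
    """
    xd, wd = x.data, weight.data
    B, C, T = xd.shape
    Co, Ci, K = wd.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input has {C}, weight expects {Ci}")
    pad = (K - 1) * dilation
    xp = np.pad(xd, ((0, 0), (0, 0), (pad, 0)))
    To = -(-T // stride)
    span = (To - 1) * stride + 1

    def tap_slice(i: int) -> slice:
        start = pad - i * dilation
        return slice(start, start + span, stride)

    y = np.zeros((B, Co, To))
    for i in range(K):
        y += np.einsum("oc,bct->bot", wd[:, :, i], xp[:, :, tap_slice(i)])
    if bias is not None:
        y += bias.data[None, :, None]

    prev = (x, weight) if bias is None else (x, weight, bias)
    req = any(t.requires_grad for t in prev)
    out = Tensor(y, requires_grad=req, _prev=prev)

    def _backward(g):
        if weight.requires_grad:
            gw = np.empty_like(wd)
            for i in range(K):
                gw[:, :, i] = np.einsum("bot,bct->oc", g, xp[:, :, tap_slice(i)])
            weight._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(K):
                gxp[:, :, tap_slice(i)] += np.einsum("oc,bot->bct", wd[:, :, i], g)
            x._accumulate(gxp[:, :, pad:])
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))

    out._backward = _backward if req else None
    return out
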