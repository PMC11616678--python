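"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float32 array and records a backward closure;
:meth:`Tensor.backward` walks the graph in reverse topological order. The op
set is deliberately small — exactly what a small transformer needs: broadcast
arithmetic, batched matmul, reshape/transpose, embedding gather, relu, fused
softmax / layer-norm / masked cross-entropy, dropout. Gradients accumulate
in ``.grad`` as plain numpy arrays.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

_GRAD_ENABLED = True
DTYPE = np.float32


def set_dtype(dtype) -> None:
    """Switch the engine's float width (float64 eases numerical gradient checks)."""
    global DTYPE
    DTYPE = np.dtype(dtype).type


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward: Optional[Callable[[], None]] = None
        self._prev: Tuple["Tensor", ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray, fresh: bool = False) -> None:
        """Add ``grad`` to ``.grad``.

        ``fresh=True`` promises the array is a temporary owned by the caller
        (never a view of another node's gradient), letting us adopt it
        without a defensive copy.
        """
        if self.grad is None:
            if fresh and grad.dtype == self.data.dtype:
                self.grad = grad
            else:
                self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        topo: List[Tensor] = []
        visited = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in visited:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # release closures and parent links: they form reference cycles that
        # would otherwise keep every intermediate array alive until a GC pass
        for node in topo:
            node._backward = None
            node._prev = ()
            if node is not self and not node.requires_grad:
                node.grad = None

    # ------------------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _make(np.add(self.data, other.data), (self, other))
        if out.requires_grad:

            def _bw():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad, other.data.shape))

            out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _make(np.multiply(self.data, other.data), (self, other))
        if out.requires_grad:

            def _bw():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape), fresh=True)
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape), fresh=True)

            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _make(np.matmul(self.data, other.data), (self, other))
        if out.requires_grad:

            def _bw():
                g = out.grad
                if self.requires_grad:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                    self._accumulate(_unbroadcast(ga, self.data.shape), fresh=True)
                if other.requires_grad:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accumulate(_unbroadcast(gb, other.data.shape), fresh=True)

            out._backward = _bw
        return out

    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))
        if out.requires_grad:

            def _bw():
                self._accumulate(out.grad.reshape(self.data.shape))

            out._backward = _bw
        return out

    def transpose(self, *axes):
        out = _make(self.data.transpose(*axes), (self,))
        if out.requires_grad:
            inverse = np.argsort(axes)

            def _bw():
                self._accumulate(out.grad.transpose(*inverse))

            out._backward = _bw
        return out


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
    return out


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather ``weight[idx]``; backward scatter-adds into the table."""
    idx = np.asarray(idx)
    out = _make(weight.data[idx], (weight,))
    if out.requires_grad:

        def _bw():
            np.add.at(weight.grad_buffer(), idx, out.grad)

        out._backward = _bw
    return out


def pad_rows(x: Tensor, before: int, after: int) -> Tensor:
    """Zero-pad along axis 0 (used to build symmetric convolution windows)."""
    n = x.data.shape[0]
    pads = [(before, after)] + [(0, 0)] * (x.data.ndim - 1)
    out = _make(np.pad(x.data, pads), (x,))
    if out.requires_grad:

        def _bw():
            x._accumulate(out.grad[before : before + n])

        out._backward = _bw
    return out


def relu(x: Tensor) -> Tensor:
    out = _make(np.maximum(x.data, 0.0), (x,))
    if out.requires_grad:

        def _bw():
            x._accumulate(out.grad * (x.data > 0), fresh=True)

        out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _make(y, (x,))
    if out.requires_grad:

        def _bw():
            g = out.grad
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot), fresh=True)

        out._backward = _bw
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = _make(xhat * gain.data + bias.data, (x, gain, bias))
    if out.requires_grad:

        def _bw():
            g = out.grad
            if bias.requires_grad:
                bias._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))
            if gain.requires_grad:
                gain._accumulate((g * xhat).reshape(-1, g.shape[-1]).sum(axis=0))
            if x.requires_grad:
                gx = g * gain.data
                n = x.data.shape[-1]
                dx = (
                    gx
                    - gx.mean(axis=-1, keepdims=True)
                    - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                ) * inv
                x._accumulate(dx, fresh=True)

        out._backward = _bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(DTYPE) / (1.0 - p)
    return x * Tensor(keep)


def cross_entropy(
    logits: Tensor,
    targets: np.ndarray,
    mask: Optional[np.ndarray] = None,
    count_mask: Optional[np.ndarray] = None,
) -> Tuple[Tensor, float, int]:
    """Masked mean token cross-entropy.

    Returns ``(loss, n_correct, n_tokens)`` where correctness is argmax
    agreement on unmasked positions. ``logits`` is (N, V); ``targets`` (N,).
    ``count_mask`` optionally restricts which positions enter the
    correct/total counts (the loss always follows ``mask``).
    """
    targets = np.asarray(targets).reshape(-1)
    n, v = logits.data.shape
    if mask is None:
        mask = np.ones(n, dtype=DTYPE)
    mask = np.asarray(mask, dtype=DTYPE).reshape(-1)
    total = float(mask.sum())
    if total == 0:
        raise ValueError("cross_entropy: empty mask")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    nll = -(logp[np.arange(n), targets] * mask).sum() / total
    out = _make(DTYPE(nll), (logits,))
    if out.requires_grad:

        def _bw():
            probs = np.exp(logp)
            probs[np.arange(n), targets] -= 1.0
            probs *= (mask / total)[:, None]
            logits._accumulate(probs * out.grad, fresh=True)

        out._backward = _bw
    cmask = mask if count_mask is None else np.asarray(count_mask, dtype=DTYPE).reshape(-1)
    correct = int(((logp.argmax(axis=1) == targets) * cmask).sum())
    return out, correct, int(cmask.sum())


# convenience for scatter-add into parameters
def _grad_buffer(self: Tensor) -> np.ndarray:
    if self.grad is None:
        self.grad = np.zeros_like(self.data)
    return self.grad


Tensor.grad_buffer = _grad_buffer
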