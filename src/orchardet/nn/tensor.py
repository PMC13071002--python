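"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The detection blocks in this package are small enough that a compact
tape-based engine is sufficient: every operation records a backward
closure, and :meth:`Tensor.backward` walks the graph in reverse
topological order.  Arrays are kept in float64 so that the analytic
oracles used in the test-suite can be checked at tight tolerances.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "MAC_COUNTER"]

# global multiply-accumulate counter used by analytic FLOP estimation;
# incremented by matmul and conv2d when enabled
MAC_COUNTER = {"enabled": False, "macs": 0}


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this tensor through the recorded graph."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---------------------------- arithmetic --------------------------
    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + o.data, _prev=(self, o))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g, o.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * o.data, _prev=(self, o))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * o.data, self.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g * self.data, o.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        return self * o ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * p * self.data ** (p - 1), self.shape))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(np.matmul(self.data, o.data), _prev=(self, o))
        if MAC_COUNTER["enabled"]:
            MAC_COUNTER["macs"] += int(np.prod(out.shape)) * self.shape[-1]

        def _bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(o.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if o.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                o._accumulate(_unbroadcast(gb, o.shape))

        out._backward = _bw
        return out

    # ---------------------------- shaping -----------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        out._backward = _bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = _bw
        return out

    def pad2d(self, pad_h: tuple[int, int], pad_w: tuple[int, int]):
        """Zero-pad the trailing two (spatial) axes."""
        pads = [(0, 0)] * (self.ndim - 2) + [pad_h, pad_w]
        out = Tensor(np.pad(self.data, pads), _prev=(self,))
        sl = tuple(
            [slice(None)] * (self.ndim - 2)
            + [
                slice(pad_h[0], out.shape[-2] - pad_h[1]),
                slice(pad_w[0], out.shape[-1] - pad_w[1]),
            ]
        )

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g[sl])

        out._backward = _bw
        return out

    # ---------------------------- elementwise -------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * y)

        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = _bw
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * y * (1.0 - y))

        out._backward = _bw
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - y * y))

        out._backward = _bw
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = _bw
        return out

    def abs(self):
        s = np.sign(self.data)
        out = Tensor(np.abs(self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * s)

        out._backward = _bw
        return out

    def sqrt(self):
        return self ** 0.5

    # ---------------------------- reductions --------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        y = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == y)
        # split gradient over ties for a well-defined subgradient
        mask = mask / mask.sum(axis=axis, keepdims=True)
        out_data = y if keepdims else np.squeeze(y, axis=axis)
        out = Tensor(out_data, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(mask * g)

        out._backward = _bw
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accumulate(s * (g - dot))

        out._backward = _bw
        return out


class Parameter(Tensor):
    """A tensor flagged as trainable."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _prev=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = _bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.stack(datas, axis=axis), _prev=tuple(tensors))

    def _bw(g):
        slices = np.split(g, len(tensors), axis=axis)
        for t, gs in zip(tensors, slices):
            if t.requires_grad:
                t._accumulate(np.squeeze(gs, axis=axis))

    out._backward = _bw
    return out
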