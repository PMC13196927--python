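"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operator set needed by the ECG models in this
package: broadcast arithmetic, matmul (batched), reductions, shape ops, a
strided/padded 1-D convolution, elementwise nonlinearities and a numerically
stable softplus.  Gradients follow the standard vector-Jacobian-product rules;
broadcasting is undone by summing over broadcast axes.  Correctness is pinned
down by a central-difference gradient check in the test suite.

Arrays keep whatever float dtype they are given; float32 is used for training
speed, float64 for gradient checks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv1d", "softmax", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)

        def bwd(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def bwd(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data * other.data))

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bwd)

    def __matmul__(self, other):
        other = self._coerce(other)

        def bwd(g):
            self._accum(np.matmul(g, np.swapaxes(other.data, -1, -2)))
            other._accum(np.matmul(np.swapaxes(self.data, -1, -2), g))

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bwd)

    # -- elementwise -------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bwd)

    def abs(self):
        def bwd(g):
            self._accum(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), bwd)

    def sigmoid(self):
        # stable: expit via tanh identity
        out_data = 0.5 * (np.tanh(0.5 * self.data) + 1.0)

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def silu(self):
        """Sigmoid-weighted linear unit x * sigmoid(x) (a.k.a. Swish)."""
        s = 0.5 * (np.tanh(0.5 * self.data) + 1.0)
        out_data = self.data * s

        def bwd(g):
            self._accum(g * (s + self.data * s * (1.0 - s)))

        return Tensor._make(out_data, (self,), bwd)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)
        s = 0.5 * (np.tanh(0.5 * self.data) + 1.0)

        def bwd(g):
            self._accum(g * s)

        return Tensor._make(out_data, (self,), bwd)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is zero outside [lo, hi]."""
        mask = (self.data >= lo) & (self.data <= hi)

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bwd)

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def repeat_time(self, factor: int):
        """Repeat each sample `factor` times along the last axis (upsampling)."""
        def bwd(g):
            self._accum(g.reshape(*self.data.shape, factor).sum(axis=-1))

        return Tensor._make(np.repeat(self.data, factor, axis=-1), (self,), bwd)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """1-D convolution (cross-correlation): x [N,C,T], w [O,C,K], b [O].

    im2col + GEMM forward; backward reuses the column matrix for the weight
    gradient and scatters columns back for the input gradient.
    """
    N, C, T = x.data.shape
    O, Cw, K = w.data.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    Tp = xp.shape[-1]
    T_out = (Tp - K) // stride + 1
    if T_out <= 0:
        raise ValueError("kernel longer than padded input")
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)[:, :, ::stride, :]
    # cols: [N, T_out, C*K]
    cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(N, T_out, C * K)
    wmat = w.data.reshape(O, C * K)
    out_data = cols @ wmat.T  # [N, T_out, O]
    if b is not None:
        out_data = out_data + b.data
    out_data = np.ascontiguousarray(out_data.transpose(0, 2, 1))  # [N, O, T_out]

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 1))  # [N, T_out, O]
        if b is not None:
            b._accum(gt.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = np.tensordot(gt, cols, axes=([0, 1], [0, 1]))  # [O, C*K]
            w._accum(gw.reshape(O, C, K))
        if x.requires_grad:
            gcols = gt @ wmat  # [N, T_out, C*K]
            gcols = gcols.reshape(N, T_out, C, K).transpose(0, 2, 1, 3)  # [N,C,T_out,K]
            gxp = np.zeros((N, C, Tp), dtype=g.dtype)
            for k in range(K):
                gxp[:, :, k:k + stride * T_out:stride] += gcols[:, :, :, k]
            x._accum(gxp[:, :, padding:Tp - padding] if padding else gxp)

    return Tensor._make(out_data, parents, bwd)
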