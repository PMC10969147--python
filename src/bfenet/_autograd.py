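"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations the network needs are implemented: broadcast-aware
arithmetic, batched matrix products, reductions, a handful of nonlinearities,
valid 1-D convolution and max pooling along the last axis, softmax /
log-softmax, and inverted dropout. Gradients are accumulated by a topological
sweep from the loss node. Everything runs in float64; the gradient of every
primitive is checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the closure that routes gradients to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        # first write stores the array; later writes allocate a fresh sum, so
        # grad buffers may alias upstream arrays but are never mutated in place
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        """Backpropagate from this node (a scalar unless ``grad`` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._node(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accumulate(-g)

        return Tensor._node(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._node(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (Tensor._lift(other) ** -1.0)

    def __rtruediv__(self, other):
        return Tensor._lift(other) * (self ** -1.0)

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)
        out_data = a.data ** p

        def bw(g):
            a._accumulate(g * p * a.data ** (p - 1.0))

        return Tensor._node(out_data, (a,), bw)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        # stacked @ matrix: collapse leading axes into one GEMM instead of
        # letting numpy loop over the batch
        if a.data.ndim > 2 and b.data.ndim == 2:
            lead = a.data.shape[:-1]
            k = a.data.shape[-1]
            a2 = a.data.reshape(-1, k)
            out_data = (a2 @ b.data).reshape(*lead, b.data.shape[1])

            def bw(g):
                g2 = g.reshape(-1, b.data.shape[1])
                if a.requires_grad:
                    a._accumulate((g2 @ b.data.T).reshape(a.data.shape))
                if b.requires_grad:
                    b._accumulate(a2.T @ g2)

            return Tensor._node(out_data, (a, b), bw)

        def bw(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._node(np.matmul(a.data, b.data), (a, b), bw)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bw(g):
            a._accumulate(g.reshape(old))

        return Tensor._node(a.data.reshape(shape), (a,), bw)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def bw(g):
            a._accumulate(np.swapaxes(g, ax1, ax2))

        return Tensor._node(np.swapaxes(a.data, ax1, ax2), (a,), bw)

    @property
    def mT(self):
        return self.swapaxes(-1, -2)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = g
            if not keepdims and axis is not None:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                axes = tuple(ax % a.data.ndim for ax in axes)
                gg = np.expand_dims(g, axes)
            a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._node(out, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -------------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accumulate(g * mask)

        return Tensor._node(a.data * mask, (a,), bw)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accumulate(g * out_data)

        return Tensor._node(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accumulate(g / a.data)

        return Tensor._node(np.log(a.data), (a,), bw)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            a._accumulate(g * (1.0 - out_data ** 2))

        return Tensor._node(out_data, (a,), bw)

    def gelu(self):
        """Gaussian error linear unit (tanh approximation), single graph node."""
        a = self
        c = np.sqrt(2.0 / np.pi)
        x = a.data
        t = np.tanh(c * (x + 0.044715 * x * x * x))
        out_data = 0.5 * x * (1.0 + t)

        def bw(g):
            dt = (1.0 - t * t) * c * (1.0 + 3 * 0.044715 * x * x)
            a._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return Tensor._node(out_data, (a,), bw)

    def softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot))

        return Tensor._node(out_data, (a,), bw)

    def log_softmax(self, axis: int = -1):
        a = self
        m = a.data.max(axis=axis, keepdims=True)
        shifted = a.data - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        soft = np.exp(out_data)

        def bw(g):
            a._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

        return Tensor._node(out_data, (a,), bw)

    # -- structured ops -------------------------------------------------------

    def conv1d(self, weight: "Tensor", bias: "Tensor"):
        """Valid cross-correlation along the last axis.

        self: (B, C_in, L); weight: (C_out, C_in, K); bias: (C_out,).
        Output: (B, C_out, L - K + 1).
        """
        a, w, b = self, weight, bias
        K = w.data.shape[-1]
        if a.data.shape[-1] < K:
            raise ValueError(
                f"conv1d: input length {a.data.shape[-1]} shorter than kernel {K}"
            )
        B, Cin, L = a.data.shape
        Cout = w.data.shape[0]
        Lo = L - K + 1
        # materialize windows as a contiguous (B, Lo, Cin*K) matrix: matmul is
        # far faster than einsum over the strided sliding-window view
        win = np.ascontiguousarray(
            np.lib.stride_tricks.sliding_window_view(a.data, K, axis=2).transpose(0, 2, 1, 3)
        ).reshape(B, Lo, Cin * K)
        wmat = w.data.reshape(Cout, Cin * K)
        out_data = (win @ wmat.T).transpose(0, 2, 1) + b.data[None, :, None]

        def bw(g):
            gmat = np.ascontiguousarray(g.transpose(0, 2, 1))  # (B, Lo, Cout)
            if w.requires_grad:
                gw = np.tensordot(gmat, win, axes=([0, 1], [0, 1]))  # (Cout, Cin*K)
                w._accumulate(gw.reshape(Cout, Cin, K))
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2)))
            if a.requires_grad:
                gwin = gmat @ wmat  # (B, Lo, Cin*K)
                gx = np.zeros_like(a.data)
                gwin = gwin.reshape(B, Lo, Cin, K)
                for kk in range(K):  # scatter-add window gradients back
                    gx[:, :, kk : kk + Lo] += gwin[:, :, :, kk].transpose(0, 2, 1)
                a._accumulate(gx)

        return Tensor._node(out_data, (a, w, b), bw)

    def maxpool1d(self, pool: int):
        """Non-overlapping max pooling along the last axis (trailing remainder dropped)."""
        a = self
        B = a.data.shape[:-1]
        L = a.data.shape[-1]
        Lo = L // pool
        if Lo < 1:
            raise ValueError(f"maxpool1d: length {L} shorter than pool {pool}")
        xr = a.data[..., : Lo * pool].reshape(*B, Lo, pool)
        idx = xr.argmax(axis=-1)
        out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def bw(g):
            gr = np.zeros_like(xr)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gx = np.zeros_like(a.data)
            gx[..., : Lo * pool] = gr.reshape(*B, Lo * pool)
            a._accumulate(gx)

        return Tensor._node(out_data, (a,), bw)

    def dropout(self, rate: float, rng: np.random.Generator, training: bool):
        """Inverted dropout; identity when not training or rate == 0."""
        if not training or rate <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= rate) / (1.0 - rate)
        return self * mask


def constant(x) -> Tensor:
    """Wrap an array as a non-differentiable tensor."""
    return Tensor(x, requires_grad=False)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._node(out_data, tensors, bw)
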