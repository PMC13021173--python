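"""Compact reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` accumulates gradients through the recorded graph
in reverse topological order.  The op set is exactly what the attention
blocks, the noise-conditioned classifier and the diffusion denoiser need:
broadcast arithmetic, matmul, stride-1 grouped 2-D convolution, the usual
activations, and reductions including max and lower-median pooling.

All computation is float64; determinism is inherited from numpy.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @classmethod
    def _make(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS post-order
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                stack.pop()
                topo.append(node)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if pg is None or not parent.requires_grad:
                        continue
                    key = id(parent)
                    grads[key] = pg if key not in grads else grads[key] + pg

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        return Tensor._make(
            self.data**exponent,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other):
        other = self._wrap(other)
        return Tensor._make(
            self.data @ other.data,
            (self, other),
            lambda g: (g @ other.data.T, self.data.T @ g),
        )

    def __getitem__(self, key):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)

        return Tensor._make(self.data[key], (self,), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(self.shape),)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.full_like(self.data, 1.0) * g,)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along one axis; ties route the gradient to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)

        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), gg, axis=axis)
            return (full,)

        return Tensor._make(out if keepdims else np.squeeze(out, axis), (self,), backward)

    def median_lower(self, axis: int, keepdims: bool = False):
        """Lower median along one axis (deterministic tie-break to the stable
        sort position); the gradient flows to the selected element only."""
        order = np.argsort(self.data, axis=axis, kind="stable")
        k = (self.shape[axis] - 1) // 2
        idx = np.take(order, k, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)

        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), gg, axis=axis)
            return (full,)

        return Tensor._make(out if keepdims else np.squeeze(out, axis), (self,), backward)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(
            out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),)
        )

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    def gelu(self):
        """Exact GELU: x·Φ(x) with the Gaussian CDF via erf."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
        return Tensor._make(x * phi, (self,), lambda g: (g * (phi + x * pdf),))

    def softmax(self, axis: int):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return (out_data * (g - dot),)

        return Tensor._make(out_data, (self,), backward)

    def log_softmax(self, axis: int):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        soft = np.exp(out_data)

        def backward(g):
            return (g - soft * g.sum(axis=axis, keepdims=True),)

        return Tensor._make(out_data, (self,), backward)

    # -- convolution ------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               padding: tuple[int, int] = (0, 0), groups: int = 1) -> "Tensor":
        """Stride-1 grouped 2-D convolution (cross-correlation convention).

        ``self``: (B, Cin, H, W); ``weight``: (Cout, Cin//groups, KH, KW);
        output spatial size H+2ph−KH+1 × W+2pw−KW+1.
        """
        x, w = self.data, weight.data
        B, Cin, H, W = x.shape
        Cout, Cin_g, KH, KW = w.shape
        ph, pw = padding
        assert Cin == Cin_g * groups and Cout % groups == 0
        Cout_g = Cout // groups
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        Ho, Wo = H + 2 * ph - KH + 1, W + 2 * pw - KW + 1
        xg = xp.reshape(B, groups, Cin_g, H + 2 * ph, W + 2 * pw)
        wg = w.reshape(groups, Cout_g, Cin_g, KH, KW)
        out = np.zeros((B, groups, Cout_g, Ho, Wo))
        for ki in range(KH):
            for kj in range(KW):
                xs = xg[:, :, :, ki : ki + Ho, kj : kj + Wo]
                out += np.einsum("bgchw,goc->bgohw", xs, wg[:, :, :, ki, kj])
        out = out.reshape(B, Cout, Ho, Wo)
        if bias is not None:
            out = out + bias.data.reshape(1, Cout, 1, 1)

        def backward(g):
            gg = g.reshape(B, groups, Cout_g, Ho, Wo)
            dxp = np.zeros_like(xg)
            dw = np.zeros_like(wg)
            for ki in range(KH):
                for kj in range(KW):
                    xs = xg[:, :, :, ki : ki + Ho, kj : kj + Wo]
                    dw[:, :, :, ki, kj] = np.einsum("bgohw,bgchw->goc", gg, xs)
                    dxp[:, :, :, ki : ki + Ho, kj : kj + Wo] += np.einsum(
                        "bgohw,goc->bgchw", gg, wg[:, :, :, ki, kj]
                    )
            dx = dxp.reshape(B, Cin, H + 2 * ph, W + 2 * pw)
            dx = dx[:, :, ph : ph + H, pw : pw + W]
            db = g.sum(axis=(0, 2, 3)) if bias is not None else None
            grads = [dx, dw.reshape(Cout, Cin_g, KH, KW)]
            if bias is not None:
                grads.append(db)
            return tuple(grads)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._make(
        np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )
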