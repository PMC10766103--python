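"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the classifier needs: broadcasting
arithmetic, matmul, strided 2-D convolution (im2col), pointwise
nonlinearities, reductions and shape manipulation.  Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`, which
topologically sorts the recorded tape.  Float32 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            return g @ other.data.T, self.data.T @ g

        return self._make(self.data @ other.data, (self, other), backward)

    # -- pointwise nonlinearities ---------------------------------------------
    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def tanh(self):
        t = np.tanh(self.data)
        return self._make(t, (self,), lambda g: (g * (1 - t**2),))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(s, (self,), lambda g: (g * s * (1 - s),))

    def exp(self):
        e = np.exp(self.data)
        return self._make(e, (self,), lambda g: (g * e,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        r = np.sqrt(self.data)
        return self._make(r, (self,), lambda g: (g / (2 * r),))

    # -- reductions / shape ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).astype(np.float32),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).astype(np.float32),)

        return self._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.shape
        return self._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return self._make(
            self.data.transpose(*axes), (self,), lambda g: (g.transpose(*inv),)
        )

    @property
    def T(self):
        return self.transpose(*reversed(range(self.data.ndim)))

    # -- convolution -----------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2-D convolution (cross-correlation) via im2col.

        self: (B, Cin, H, W); weight: (Cout, Cin, kh, kw); bias: (Cout,).
        """
        x, w = self.data, weight.data
        B, Cin, H, W = x.shape
        Cout, _, kh, kw = w.shape
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        Hp, Wp = x.shape[2], x.shape[3]
        Ho = (Hp - kh) // stride + 1
        Wo = (Wp - kw) // stride + 1
        s0, s1, s2, s3 = x.strides
        cols = np.lib.stride_tricks.as_strided(
            x,
            shape=(B, Cin, Ho, Wo, kh, kw),
            strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        )
        cols2 = np.ascontiguousarray(
            cols.transpose(0, 2, 3, 1, 4, 5)
        ).reshape(B * Ho * Wo, Cin * kh * kw)
        wmat = w.reshape(Cout, -1)
        out = cols2 @ wmat.T
        if bias is not None:
            out = out + bias.data
        out = out.reshape(B, Ho, Wo, Cout).transpose(0, 3, 1, 2)

        def backward(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, Cout)
            gw = (gmat.T @ cols2).reshape(w.shape)
            gcols = (gmat @ wmat).reshape(B, Ho, Wo, Cin, kh, kw)
            gx = np.zeros((B, Cin, Hp, Wp), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i : i + Ho * stride : stride,
                       j : j + Wo * stride : stride] += gcols[
                        :, :, :, :, i, j
                    ].transpose(0, 3, 1, 2)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            grads = [gx, gw]
            if bias is not None:
                grads.append(gmat.sum(axis=0))
            return tuple(grads)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out, parents, backward)

    # -- composite helpers -------------------------------------------------------
    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self - Tensor(m)
        lse = shifted.exp().sum(axis=axis, keepdims=True).log()
        return shifted - lse

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    def l2_normalize(self, axis: int = -1, eps: float = 1e-12):
        norm = (self * self).sum(axis=axis, keepdims=True).sqrt()
        return self / (norm + eps)

    # -- backward pass -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None or node._backward is None:
                if g is not None and node.requires_grad:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad:
                    continue
                pg = np.asarray(pg, dtype=np.float32)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis, differentiable."""
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g):
            return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

        out._backward = backward
    return out
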