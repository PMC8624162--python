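"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package needs exact gradients in three places: maximum-likelihood
training of the coupling subnetworks and conditioning networks, gradient
flow from the flow's log-determinant into the subnetworks, and the
image-space gradient of ``-log p(x|y)`` used by variational sample
refinement.  A small tape-based engine over ``numpy.float64`` covers all
three; every primitive's backward rule is checked against central finite
differences in the test suite.

Only the operations the flow layers actually use are implemented.  All
arithmetic follows numpy broadcasting; gradients of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "conv2d", "upsample2x"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
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
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        a_shape, b_shape = self.data.shape, other.data.shape
        return Tensor._make(
            out_data,
            (self, other),
            lambda g: (_unbroadcast(g, a_shape), _unbroadcast(g, b_shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        return Tensor._make(
            a * b,
            (self, other),
            lambda g: (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        return Tensor._make(
            a / b,
            (self, other),
            lambda g: (
                _unbroadcast(g / b, a.shape),
                _unbroadcast(-g * a / (b * b), b.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        a = self.data
        return Tensor._make(a**p, (self,), lambda g: (g * p * a ** (p - 1),))

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        out = a @ b

        def backward(g):
            if a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2)
            else:
                ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
            if b.ndim == 1:
                gb = np.swapaxes(a, -1, -2) @ g
            else:
                gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return ga, gb

        return Tensor._make(out, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        a = self.data
        return Tensor._make(np.log(a), (self,), lambda g: (g / a,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), lambda g: (g * 0.5 / out,))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, (self,), lambda g: (g * (1.0 - out * out),))

    def leaky_relu(self, slope: float = 0.1):
        a = self.data
        mask = np.where(a > 0, 1.0, slope)
        return Tensor._make(a * mask, (self,), lambda g: (g * mask,))

    def abs(self):
        a = self.data
        sign = np.sign(a)
        return Tensor._make(np.abs(a), (self,), lambda g: (g * sign,))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a_shape = self.data.shape
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, a_shape).copy(),)
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % len(a_shape) for ax in axes)
            if not keepdims:
                for ax in sorted(axes):
                    g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, a_shape).copy(),)

        return Tensor._make(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a_shape = self.data.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(a_shape),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        a_shape = self.data.shape

        def backward(g):
            out = np.zeros(a_shape)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(self.data[idx], (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def _conv2d_raw(x, w, b, stride, pad):
    """Direct conv as a sum of shifted 1x1 convs; x (B,C,H,W), w (O,C,k,k)."""
    B, C, H, W = x.shape
    O, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    OH = (H + 2 * pad - k) // stride + 1
    OW = (W + 2 * pad - k) // stride + 1
    out = np.zeros((B, O, OH, OW))
    for ki in range(k):
        for kj in range(k):
            xs = xp[:, :, ki : ki + OH * stride : stride, kj : kj + OW * stride : stride]
            out += np.einsum("oc,bchw->bohw", w[:, :, ki, kj], xs, optimize=True)
    if b is not None:
        out += b.reshape(1, O, 1, 1)
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) with zero padding."""
    x, w = as_tensor(x), as_tensor(w)
    parents = [x, w] + ([b] if b is not None else [])
    xd, wd = x.data, w.data
    bd = b.data if b is not None else None
    out = _conv2d_raw(xd, wd, bd, stride, pad)

    def backward(g):
        B, C, H, W = xd.shape
        O, _, k, _ = wd.shape
        OH, OW = g.shape[2], g.shape[3]
        xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(wd)
        for ki in range(k):
            for kj in range(k):
                sl_i = slice(ki, ki + OH * stride, stride)
                sl_j = slice(kj, kj + OW * stride, stride)
                xs = xp[:, :, sl_i, sl_j]
                gw[:, :, ki, kj] = np.einsum("bohw,bchw->oc", g, xs, optimize=True)
                gxp[:, :, sl_i, sl_j] += np.einsum(
                    "oc,bohw->bchw", wd[:, :, ki, kj], g, optimize=True
                )
        gx = gxp[:, :, pad : pad + H, pad : pad + W] if pad else gxp
        grads = [gx, gw]
        if bd is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return Tensor._make(out, parents, backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of a (B,C,H,W) tensor."""
    x = as_tensor(x)
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        B, C, H2, W2 = g.shape
        return (g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)),)

    return Tensor._make(out, (x,), backward)
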