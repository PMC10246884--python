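"""Minimal reverse-mode autodiff on NumPy arrays.

Supports exactly the operations the segmentation and generative networks
need: broadcasting arithmetic, matmul (optionally batched), reductions,
elementwise nonlinearities, shape manipulation, 2-D convolution via
im2col/col2im, 2x2 max pooling, nearest-neighbor upsampling, instance
normalization and embedding-row lookup.  Gradients are accumulated through
a topologically sorted tape.

Arrays default to float32; float64 inputs are kept as-is (useful for
numerical gradient checks).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _as_array(data):
    arr = np.asarray(data)
    if arr.dtype.kind in "iub":
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and not t._parents:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out = self._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return self._make(
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
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p
        return self._make(
            out_data, (self,), lambda g: (g * p * self.data ** (p - 1),)
        )

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis if isinstance(axis, int) else tuple(axis))
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(
            out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),)
        )

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1.0 - out_data ** 2),))

    def sqrt(self):
        return self ** 0.5

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return self._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(self.shape),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return self._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    # -- structured ops ----------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor" = None, stride: int = 1,
               pad=(0, 0, 0, 0)):
        """2-D cross-correlation. x:(B,C,H,W), weight:(O,C,kh,kw).

        `pad` is (top, bottom, left, right) so 4x4 "same" stride-1 kernels
        can pad asymmetrically.
        """
        x = self.data
        w = weight.data
        B, C, H, W = x.shape
        O, Cw, kh, kw = w.shape
        if C != Cw:
            raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
        pt, pb, pl, pr = pad
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        Ho = (H + pt + pb - kh) // stride + 1
        Wo = (W + pl + pr - kw) // stride + 1
        cols = np.empty((B, C, kh, kw, Ho, Wo), dtype=x.dtype)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i, j] = xp[:, :, i:i + stride * Ho:stride,
                                      j:j + stride * Wo:stride]
        cols2 = cols.reshape(B, C * kh * kw, Ho * Wo)
        wm = w.reshape(O, C * kh * kw)
        out_data = np.matmul(wm[None], cols2).reshape(B, O, Ho, Wo)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, O, 1, 1)

        def backward(g):
            gflat = g.reshape(B, O, Ho * Wo)
            gw = np.matmul(gflat, cols2.transpose(0, 2, 1)).sum(axis=0)
            gw = gw.reshape(w.shape)
            gcols = np.matmul(wm.T[None], gflat).reshape(B, C, kh, kw, Ho, Wo)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * Ho:stride,
                        j:j + stride * Wo:stride] += gcols[:, :, i, j]
            gx = gxp[:, :, pt:pt + H, pl:pl + W]
            if bias is not None:
                gb = g.sum(axis=(0, 2, 3))
                return gx, gw, gb
            return gx, gw

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out_data, parents, backward)

    def maxpool2x2(self):
        B, C, H, W = self.shape
        if H % 2 or W % 2:
            raise ValueError("maxpool2x2 requires even spatial dimensions")
        blocks = self.data.reshape(B, C, H // 2, 2, W // 2, 2)
        out_data = blocks.max(axis=(3, 5))
        # tie-break: gradient flows to the first maximal element of each block
        flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
        arg = flat.argmax(axis=-1)
        onehot = np.eye(4, dtype=self.data.dtype)[arg]

        def backward(g):
            gb = onehot * g[..., None]
            gb = gb.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            return (gb.reshape(B, C, H, W),)

        return self._make(out_data, (self,), backward)

    def upsample_nearest2x(self):
        out_data = self.data.repeat(2, axis=-2).repeat(2, axis=-1)
        B, C, H, W = self.shape

        def backward(g):
            return (g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)),)

        return self._make(out_data, (self,), backward)

    def instance_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Per-(sample, channel) normalization over the spatial axes."""
        x = self.data
        B, C, H, W = x.shape
        M = H * W
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc ** 2).mean(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        gdat = gamma.data.reshape(1, C, 1, 1)
        out_data = xhat * gdat + beta.data.reshape(1, C, 1, 1)

        def backward(g):
            gxhat = g * gdat
            gvar = (gxhat * xc).sum(axis=(2, 3), keepdims=True) * (-0.5) * inv ** 3
            gmu = (-gxhat * inv).sum(axis=(2, 3), keepdims=True) + \
                gvar * (-2.0 * xc.mean(axis=(2, 3), keepdims=True))
            gx = gxhat * inv + gvar * 2.0 * xc / M + gmu / M
            ggamma = (g * xhat).sum(axis=(0, 2, 3))
            gbeta = g.sum(axis=(0, 2, 3))
            return gx, ggamma, gbeta

        return self._make(out_data, (self, gamma, beta), backward)

    def take_rows(self, idx):
        """Row lookup table[idx] with scatter-add gradient (embeddings)."""
        idx = np.asarray(idx, dtype=np.int64)
        out_data = self.data[idx]

        def backward(g):
            gt = np.zeros_like(self.data)
            np.add.at(gt, idx, g)
            return (gt,)

        return self._make(out_data, (self,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out
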