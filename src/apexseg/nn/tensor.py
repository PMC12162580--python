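"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network family in :mod:`apexseg.arch` needs only a small, fixed set of
differentiable primitives (dense/convolutional linear maps, 2x2 pooling and
up-sampling, softmax, layer normalisation and elementwise arithmetic), so the
engine implements exactly those as a dynamic tape: every :class:`Tensor`
records its parents and a closure that scatters the output gradient back to
them.  Convolutions are evaluated as im2col + matmul and differentiated with
the transposed convolution / column-matmul identities, so all heavy lifting
stays inside BLAS.

All arrays are float64 unless the caller supplies float32; gradients always
match the data dtype.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "relu", "softmax", "logsumexp",
           "layer_norm", "conv2d", "conv_transpose2x2", "maxpool2x2"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        if isinstance(data, np.ndarray):
            self.data = data
        elif isinstance(data, np.generic):        # 0-d numpy scalar
            self.data = np.asarray(data)
        else:
            self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- properties -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff core ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every ancestor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad += grad

    # -- elementwise arithmetic ------------------------------------------
    @staticmethod
    def _lift(x, like: np.ndarray | None = None) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        dtype = like.dtype if like is not None and np.isscalar(x) else None
        return Tensor(np.asarray(x, dtype=dtype or np.float64))

    def __add__(self, other):
        other = Tensor._lift(other, self.data)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        out._backward = bwd if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bwd(g):
            self._accum(-g)
        out._backward = bwd if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other, self.data))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other, self.data)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = bwd if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other, self.data)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -g * self.data / other.data ** 2, other.shape))
        out._backward = bwd if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))
        out._backward = bwd if out.requires_grad else None
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))

        def bwd(g):
            self._accum(g * out.data)
        out._backward = bwd if out.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def bwd(g):
            self._accum(g / self.data)
        out._backward = bwd if out.requires_grad else None
        return out

    # -- linear algebra ---------------------------------------------------
    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))
        out._backward = bwd if out.requires_grad else None
        return out

    # -- shape manipulation ----------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def bwd(g):
            self._accum(g.reshape(orig))
        out._backward = bwd if out.requires_grad else None
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))

        def bwd(g):
            self._accum(g.transpose(inv))
        out._backward = bwd if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)
        out._backward = bwd if out.requires_grad else None
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())
        out._backward = bwd if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along one axis; ties route gradient to the first max."""
        data = self.data.max(axis=axis, keepdims=True)
        idx = self.data.argmax(axis=axis)
        out_data = data if keepdims else np.squeeze(data, axis=axis)
        out = Tensor(out_data, _parents=(self,))

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis)
            self._accum(full)
        out._backward = bwd if out.requires_grad else None
        return out


# -- free functions -------------------------------------------------------

def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(gpart)
    out._backward = bwd if out.requires_grad else None
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _parents=(x,))

    def bwd(g):
        x._accum(g * (x.data > 0))
    out._backward = bwd if out.requires_grad else None
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, _parents=(x,))

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))
    out._backward = bwd if out.requires_grad else None
    return out


def logsumexp(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    se = e.sum(axis=axis, keepdims=True)
    val = m + np.log(se)
    out_data = val if keepdims else np.squeeze(val, axis=axis)
    out = Tensor(out_data, _parents=(x,))
    soft = e / se

    def bwd(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accum(g * soft)
    out._backward = bwd if out.requires_grad else None
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data, _parents=(x, gamma, beta))

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            n = x.shape[-1]
            gx = g * gamma.data
            dxhat = gx * inv
            dvar = (gx * xc).sum(-1, keepdims=True) * (-0.5) * inv ** 3
            dmu = (-dxhat).sum(-1, keepdims=True) + \
                dvar * (-2.0 / n) * xc.sum(-1, keepdims=True)
            x._accum(dxhat + dvar * 2.0 / n * xc + dmu / n)
    out._backward = bwd if out.requires_grad else None
    return out


# -- convolution primitives ------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N, C*kh*kw, OH*OW) patch matrix (stride 1)."""
    n, c, hp, wp = xp.shape
    oh, ow = hp - kh + 1, wp - kw + 1
    s0, s1, s2, s3 = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2, s3))
    return win.reshape(n, c * kh * kw, oh * ow)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: int | None = None) -> Tensor:
    """2-D cross-correlation, stride 1.

    ``x``: (N,C,H,W); ``w``: (O,C,kh,kw); default padding is "same"
    (kh//2) so odd kernels preserve the spatial shape.
    """
    kh, kw = w.shape[2], w.shape[3]
    if padding is None:
        padding = kh // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2)) \
        if padding else x.data
    n, c = x.shape[0], x.shape[1]
    oh = xp.shape[2] - kh + 1
    ow = xp.shape[3] - kw + 1
    cols = _im2col(xp, kh, kw)                       # (N, CK, P)
    wm = w.data.reshape(w.shape[0], -1)              # (O, CK)
    y = np.matmul(wm, cols).reshape(n, w.shape[0], oh, ow)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _parents=parents)

    def bwd(g):
        gm = g.reshape(n, w.shape[0], oh * ow)       # (N, O, P)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.shape))
        if x.requires_grad:
            # full correlation of g with the flipped, channel-swapped kernel
            wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gp = np.pad(g, ((0, 0), (0, 0), (kh - 1,) * 2, (kw - 1,) * 2))
            gcols = _im2col(gp, kh, kw)
            wfm = wflip.reshape(c, -1)
            gx_full = np.matmul(wfm, gcols).reshape(
                n, c, gp.shape[2] - kh + 1, gp.shape[3] - kw + 1)
            if padding:
                gx_full = gx_full[:, :, padding:padding + x.shape[2],
                                  padding:padding + x.shape[3]]
            x._accum(gx_full)
    out._backward = bwd if out.requires_grad else None
    return out


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution with a 2x2 kernel and stride 2 (no overlap).

    ``x``: (N,C,H,W); ``w``: (C,O,2,2); output (N,O,2H,2W).
    """
    n, c, h, wd = x.shape
    o = w.shape[1]
    # (N,H,W,O,2,2) then interleave
    t = np.tensordot(x.data, w.data, axes=([1], [0]))
    y = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, o, 2 * h, 2 * wd)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _parents=parents)

    def bwd(g):
        gt = g.reshape(n, o, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.tensordot(x.data, gt, axes=([0, 2, 3], [0, 1, 2]))
            w._accum(gw)
        if x.requires_grad:
            gx = np.tensordot(gt, w.data, axes=([3, 4, 5], [1, 2, 3]))
            x._accum(gx.transpose(0, 3, 1, 2))
    out._backward = bwd if out.requires_grad else None
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; ties route gradient to the first max."""
    n, c, h, w = x.shape
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, _parents=(x,))

    def bwd(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accum(gx)
    out._backward = bwd if out.requires_grad else None
    return out
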