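"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

Tensors wrap float32 ndarrays and record a backward closure per operation;
``Tensor.backward()`` topologically sorts the graph and accumulates
gradients. The operation set is exactly what the segmentation networks
need: broadcast arithmetic, matmul, reductions, relu/sigmoid, reshape /
transpose / concat, axis max-pooling, im2col 2D convolution, nearest
2× upsampling, and fused stable losses. Convolutions lower to matmul so the
heavy lifting stays in BLAS.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "concat", "conv2d", "upsample2x_nearest",
           "softmax", "softmax_cross_entropy", "sigmoid_bce"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float32)}
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
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        return Tensor(self.data + other.data, parents=(self, other),
                      backward=lambda g: (_unbroadcast(g, self.shape),
                                          _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor(self.data * other.data, parents=(self, other),
                      backward=lambda g: (_unbroadcast(g * other.data, self.shape),
                                          _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return Tensor(self.data / other.data, parents=(self, other),
                      backward=lambda g: (_unbroadcast(g / other.data, self.shape),
                                          _unbroadcast(-g * self.data / other.data ** 2, other.shape)))

    def __pow__(self, p: float):
        return Tensor(self.data ** p, parents=(self,),
                      backward=lambda g: (g * p * self.data ** (p - 1),))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)

        def back(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor(np.matmul(self.data, other.data), parents=(self, other), backward=back)

    __matmul__ = matmul

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).astype(np.float32),)

        return Tensor(out, parents=(self,), backward=back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; ties share the gradient equally."""
        out = self.data.max(axis=axis, keepdims=True)

        def back(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            mask = (self.data == out)
            return (g * mask / mask.sum(axis=axis, keepdims=True),)

        return Tensor(out if keepdims else np.squeeze(out, axis=axis),
                      parents=(self,), backward=back)

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        return Tensor(self.data.reshape(*shape), parents=(self,),
                      backward=lambda g: (g.reshape(self.shape),))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(axes), parents=(self,),
                      backward=lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        def back(g):
            out = np.zeros(self.shape, dtype=np.float32)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(self.data[idx], parents=(self,), backward=back)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=(self,), backward=lambda g: (g * mask,))

    def sigmoid(self):
        s = expit(self.data)
        return Tensor(s, parents=(self,), backward=lambda g: (g * s * (1.0 - s),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor(e, parents=(self,), backward=lambda g: (g * e,))

    def log(self):
        return Tensor(np.log(self.data), parents=(self,),
                      backward=lambda g: (g / self.data,))

    def item(self) -> float:
        return float(self.data)


def concat(tensors: list, axis: int) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=back)


# ---------------------------------------------------------------------------
# Convolution (im2col) and resampling
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int):
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=np.float32)
    for u in range(kh):
        for v in range(kw):
            cols[:, :, u, v] = xp[:, :, u:u + (ho - 1) * stride + 1:stride,
                                  v:v + (wo - 1) * stride + 1:stride]
    return cols.reshape(n, c * kh * kw, ho * wo)


def _fold_edge_padding(gxp: np.ndarray, ph, pw) -> np.ndarray:
    """Route gradients of edge-replicated padding back to the border pixels
    (row fold then column fold; corners compose correctly because edge
    padding is separable)."""
    hp, wp = gxp.shape[2:]
    if ph[0]:
        gxp[:, :, ph[0]] += gxp[:, :, :ph[0]].sum(axis=2)
    if ph[1]:
        gxp[:, :, hp - ph[1] - 1] += gxp[:, :, hp - ph[1]:].sum(axis=2)
    g = gxp[:, :, ph[0]:hp - ph[1]]
    if pw[0]:
        g[:, :, :, pw[0]] += g[:, :, :, :pw[0]].sum(axis=3)
    if pw[1]:
        g[:, :, :, wp - pw[1] - 1] += g[:, :, :, wp - pw[1]:].sum(axis=3)
    return g[:, :, :, pw[0]:wp - pw[1]]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding=(0, 0), pad_mode: str = "zeros") -> Tensor:
    """2D cross-correlation. ``x``: (N,C,H,W); ``w``: (O,C,kh,kw); ``b``: (O,).

    ``padding`` is ``(ph, pw)`` or ``((top, bottom), (left, right))`` for the
    asymmetric case (needed by even kernel sizes). ``pad_mode`` is ``"zeros"``
    or ``"edge"`` (replicate the border; keeps constant inputs constant).
    """
    ph, pw = padding
    ph = (ph, ph) if np.isscalar(ph) else tuple(ph)
    pw = (pw, pw) if np.isscalar(pw) else tuple(pw)
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    assert c == c2, f"channel mismatch {c} vs {c2}"
    assert pad_mode in ("zeros", "edge")
    xp = np.pad(x.data, ((0, 0), (0, 0), ph, pw),
                mode="constant" if pad_mode == "zeros" else "edge")
    hp, wp = xp.shape[2:]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride, ho, wo)  # (N, C*kh*kw, Ho*Wo)
    out = np.matmul(w.data.reshape(o, -1), cols)  # (N, O, Ho*Wo)
    if b is not None:
        out = out + b.data[:, None]
    out = out.reshape(n, o, ho, wo)

    def back(g):
        gf = g.reshape(n, o, ho * wo)
        gw = np.matmul(gf, cols.transpose(0, 2, 1)).sum(axis=0).reshape(w.shape)
        gb = None if b is None else gf.sum(axis=(0, 2))
        gcols = np.matmul(w.data.reshape(o, -1).T, gf).reshape(n, c, kh, kw, ho, wo)
        gxp = np.zeros_like(xp)
        for u in range(kh):
            for v in range(kw):
                gxp[:, :, u:u + (ho - 1) * stride + 1:stride,
                    v:v + (wo - 1) * stride + 1:stride] += gcols[:, :, u, v]
        if pad_mode == "edge":
            gx = _fold_edge_padding(gxp, ph, pw)
        else:
            gx = gxp[:, :, ph[0]:hp - ph[1], pw[0]:wp - pw[1]]
        return (gx, gw) if b is None else (gx, gw, gb)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents=parents, backward=back)


def upsample2x_nearest(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def back(g):
        return (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

    return Tensor(out, parents=(x,), backward=back)


# ---------------------------------------------------------------------------
# Fused, numerically stable heads
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        return (p * (g - (g * p).sum(axis=axis, keepdims=True)),)

    return Tensor(p, parents=(x,), backward=back)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean pixelwise cross-entropy. ``logits``: (N,C,H,W); ``labels``:
    integer (N,H,W)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    n, c, h, w = logits.shape
    onehot_ll = np.take_along_axis(z - lse, labels[:, None], axis=1)[:, 0]
    loss = -onehot_ll.mean()

    def back(g):
        p = np.exp(z - lse)
        oh = np.zeros_like(p)
        np.put_along_axis(oh, labels[:, None], 1.0, axis=1)
        return (np.float32(g) * (p - oh) / (n * h * w),)

    return Tensor(loss, parents=(logits,), backward=back)


def sigmoid_bce(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits (stable log-sum-exp form)."""
    x, t = logits.data, targets.astype(np.float32)
    loss = (np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))).mean()

    def back(g):
        s = expit(x)
        return (np.float32(g) * (s - t) / x.size,)

    return Tensor(loss, parents=(logits,), backward=back)
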