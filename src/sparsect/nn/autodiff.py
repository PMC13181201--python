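"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operation that
produced it; ``backward()`` runs reverse-mode accumulation over the recorded
graph.  The op set is exactly what the reconstruction networks need: dense
and convolutional linear algebra, pooling/upsampling, pointwise
nonlinearities, reductions, and the custom tomography ops registered in
:mod:`sparsect.nn.ops`.

Convolution is implemented by im2col + BLAS matmul; the input gradient of a
convolution is expressed as a transposed convolution of the output gradient
(and vice versa), so stride/padding handling lives in one pair of kernels.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "stack", "stack_mean"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reverse numpy broadcasting: reduce ``grad`` down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- basic arithmetic --------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g, other.data.shape))
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g * self.data, other.data.shape))
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(-g * self.data / other.data**2,
                                           other.data.shape))
        return self._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))
        return self._make(self.data ** exponent, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)
        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        def backward(g):
            self._accum(g.reshape(old))
        return self._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, key) -> "Tensor":
        shape = self.data.shape
        def backward(g):
            gx = np.zeros(shape)
            gx[key] = g
            self._accum(gx)
        return self._make(self.data[key], (self,), backward)

    # -- pointwise ---------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        def backward(g):
            self._accum(g * mask)
        return self._make(self.data * mask, (self,), backward)

    def clamp_max(self, hi: float) -> "Tensor":
        mask = self.data < hi
        def backward(g):
            self._accum(g * mask)
        return self._make(np.minimum(self.data, hi), (self,), backward)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)
        def backward(g):
            self._accum(g * sign)
        return self._make(np.abs(self.data), (self,), backward)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)
        def backward(g):
            self._accum(g * 0.5 / out_data)
        return self._make(out_data, (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        shape = self.data.shape
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, shape).copy())
        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- convolution family -------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2-D cross-correlation. self: (N,C,H,W); weight: (O,C,kh,kw)."""
        weight = self._coerce(weight)
        x, wgt = self.data, weight.data
        out_data, cols = _conv2d_forward(x, wgt, stride, padding)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, -1, 1, 1)

        def backward(g):
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                weight._accum(_conv2d_weight_grad(cols, g, wgt.shape))
            if self.requires_grad:
                self._accum(_conv_transpose2d_forward(
                    g, wgt, stride, padding, out_size=x.shape[2:])[0])
        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out_data, parents, backward)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         stride: int = 1, padding: int = 0) -> "Tensor":
        """Transposed convolution (adjoint of conv2d with the same
        stride/padding).  self: (N,O,H,W); weight: (O,C,kh,kw) -> out (N,C,...)."""
        weight = self._coerce(weight)
        x, wgt = self.data, weight.data
        out_data, _ = _conv_transpose2d_forward(x, wgt, stride, padding)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, -1, 1, 1)

        def backward(g):
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            gx, cols = _conv2d_forward(g, wgt, stride, padding,
                                       out_size=x.shape[2:])
            if weight.requires_grad:
                weight._accum(_conv2d_weight_grad(cols, x, wgt.shape))
            if self.requires_grad:
                self._accum(gx)
        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out_data, parents, backward)

    def maxpool2(self) -> "Tensor":
        """2x2 max pooling, stride 2 (spatial dims must be even)."""
        n_, c, h, w = self.data.shape
        if h % 2 or w % 2:
            raise ValueError("maxpool2 requires even spatial dims")
        r = self.data.reshape(n_, c, h // 2, 2, w // 2, 2)
        windows = r.transpose(0, 1, 2, 4, 3, 5).reshape(n_, c, h // 2, w // 2, 4)
        arg = windows.argmax(axis=-1)
        out_data = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            gw = np.zeros((n_, c, h // 2, w // 2, 4))
            np.put_along_axis(gw, arg[..., None], g[..., None], axis=-1)
            gx = gw.reshape(n_, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._accum(gx.reshape(n_, c, h, w))
        return self._make(out_data, (self,), backward)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along an axis (used for U-Net skip fusion)."""
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Stack same-shaped tensors along a new axis."""
    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))
    return Tensor._make(np.stack([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def stack_mean(tensors: list[Tensor]) -> Tensor:
    """Mean of same-shaped scalars/tensors (loss averaging over a batch)."""
    k = len(tensors)
    out = tensors[0] * (1.0 / k)
    for t in tensors[1:]:
        out = out + t * (1.0 / k)
    return out


# -- conv kernels (shared by forward and backward paths) ---------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    """(N,C,H,W) -> (N, Ho, Wo, C*kh*kw) patch matrix."""
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    n_, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]              # (N, C, Ho, Wo, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n_, ho, wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _conv2d_forward(x: np.ndarray, w: np.ndarray, stride: int, padding: int,
                    out_size: tuple[int, int] | None = None):
    o, c, kh, kw = w.shape
    if x.shape[1] != c:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, weight expects {c}")
    cols, ho, wo = _im2col(x, kh, kw, stride, padding)
    out = cols.reshape(-1, c * kh * kw) @ w.reshape(o, -1).T
    out = out.reshape(x.shape[0], ho, wo, o).transpose(0, 3, 1, 2)
    if out_size is not None and out.shape[2:] != tuple(out_size):
        raise ValueError(f"conv2d produced {out.shape[2:]}, expected {tuple(out_size)}")
    return np.ascontiguousarray(out), cols


def _conv2d_weight_grad(cols: np.ndarray, gout: np.ndarray,
                        wshape: tuple[int, int, int, int]) -> np.ndarray:
    o = wshape[0]
    gmat = gout.transpose(0, 2, 3, 1).reshape(-1, o)       # (N*Ho*Wo, O)
    return (gmat.T @ cols.reshape(gmat.shape[0], -1)).reshape(wshape)


def _conv_transpose2d_forward(x: np.ndarray, w: np.ndarray, stride: int,
                              padding: int,
                              out_size: tuple[int, int] | None = None):
    """Adjoint of conv2d: (N,O,H,W) x (O,C,kh,kw) -> (N,C,Hout,Wout) with
    Hout = (H-1)*stride - 2*padding + kh."""
    o, c, kh, kw = w.shape
    if x.shape[1] != o:
        raise ValueError(f"conv_transpose2d: input has {x.shape[1]} channels, "
                         f"weight expects {o}")
    n_, _, h, wdt = x.shape
    # dilate by stride, pad by (k-1-padding), correlate with flipped kernel
    xd = x
    if stride > 1:
        xd = np.zeros((n_, o, (h - 1) * stride + 1, (wdt - 1) * stride + 1))
        xd[:, :, ::stride, ::stride] = x
    wf = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, O, kh, kw)
    out, _ = _conv2d_forward(xd, np.ascontiguousarray(wf), 1, kh - 1 - padding)
    if out_size is not None and out.shape[2:] != tuple(out_size):
        # asymmetric cases (output_padding) never occur for our layer configs
        raise ValueError(f"conv_transpose2d produced {out.shape[2:]}, "
                         f"expected {tuple(out_size)}")
    return out, None
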