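"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operations needed by the stain-translation networks:
broadcast-aware arithmetic, matmul, the usual pointwise nonlinearities,
reductions, reshaping, padding, nearest-neighbour upsampling, strided 2-D
convolution and fancy indexing. Gradients are accumulated by a topological
backward sweep, torch-style.

All arrays are float64; determinism is inherited from NumPy (same ops in the
same order give bit-identical results on a fixed BLAS).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = tuple(_prev)
        self._backward = _backward

    # ------------------------------------------------------------------ util
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may alias another node's gradient buffer
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self**-1.0

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    # ------------------------------------------------------------- pointwise
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1 - out.data**2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * out.data * (1 - out.data)
        )
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (self.data > 0))
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * np.where(self.data > 0, 1.0, slope)
        )
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * np.sign(self.data))
        return out

    def sqrt(self):
        return self**0.5

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def logsumexp(self, axis: int):
        # max-shifted for stability; the shift is a constant wrt gradients
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self - Tensor(m)
        return shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    # ------------------------------------------------------------- image ops
    def pad2d(self, pad: int, mode: str = "constant"):
        """Pad the last two axes by `pad` on every side."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        if mode == "constant":
            out = Tensor(np.pad(self.data, width), _prev=(self,))
            sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
            out._backward = lambda g: self.requires_grad and self._accum(g[sl])
            return out
        if mode == "reflect":
            h, w = self.shape[-2], self.shape[-1]
            ridx = np.pad(np.arange(h), pad, mode="reflect")
            cidx = np.pad(np.arange(w), pad, mode="reflect")
            out = Tensor(self.data[..., ridx[:, None], cidx], _prev=(self,))

            def bw(g):
                if not self.requires_grad:
                    return
                full = np.zeros_like(self.data)
                np.add.at(
                    full.reshape(-1, h, w).transpose(1, 2, 0),
                    (ridx[:, None], cidx),
                    g.reshape(-1, h + 2 * pad, w + 2 * pad).transpose(1, 2, 0),
                )
                self._accum(full)

            out._backward = bw
            return out
        raise ValueError(f"unknown pad mode: {mode}")

    def upsample_nearest(self, factor: int):
        """Nearest-neighbour upsampling on an (N, C, H, W) tensor."""
        out = Tensor(
            self.data.repeat(factor, axis=-2).repeat(factor, axis=-1), _prev=(self,)
        )

        def bw(g):
            if not self.requires_grad:
                return
            n, c, h, w = self.shape
            g = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
            self._accum(g)

        out._backward = bw
        return out

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None, stride: int = 1):
        """Valid (unpadded) 2-D cross-correlation on (N, C, H, W)."""
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        o, ci, kh, kw = w.shape
        if ci != c:
            raise ValueError(f"channel mismatch: input {c}, kernel {ci}")
        s = stride
        oh = (h - kh) // s + 1
        ow = (wd - kw) // s + 1
        out_data = np.zeros((n, o, oh, ow))
        for u in range(kh):
            for v in range(kw):
                xs = x[:, :, u : u + oh * s : s, v : v + ow * s : s]
                # (O,C)·(N,C,oh,ow) summed over C
                out_data += np.tensordot(w[:, :, u, v], xs, axes=([1], [1])).transpose(
                    1, 0, 2, 3
                )
        if bias is not None:
            out_data += bias.data.reshape(1, -1, 1, 1)
        prev = (self, weight) if bias is None else (self, weight, bias)
        out = Tensor(out_data, _prev=prev)

        def bw(g):
            if weight.requires_grad:
                gw = np.zeros_like(w)
                for u in range(kh):
                    for v in range(kw):
                        xs = x[:, :, u : u + oh * s : s, v : v + ow * s : s]
                        gw[:, :, u, v] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
                weight._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gx = np.zeros_like(x)
                for u in range(kh):
                    for v in range(kw):
                        # (C,O)·(N,O,oh,ow) summed over O
                        contrib = np.tensordot(
                            w[:, :, u, v], g, axes=([0], [1])
                        ).transpose(1, 0, 2, 3)
                        gx[:, :, u : u + oh * s : s, v : v + ow * s : s] += contrib
                self._accum(gx)

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out
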