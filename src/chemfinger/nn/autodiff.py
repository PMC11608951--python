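"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set needed by the fingerprint generator:
dense/convolutional layers over 1-D signals, attention, embedding lookup,
overlap-add (for differentiable inverse STFT), softmax cross-entropy and
stop-gradient for straight-through vector quantization.  All computation
is float64; gradients are accumulated, so a node may feed several
consumers.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative topological sort (deep graphs from long training loops)
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if pending:
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        return self

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return self._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(np.matmul(self.data, other.data), (self, other), backward)

    # -- elementwise ----------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def gelu(self):
        # tanh approximation, standard in transformer stacks
        c = np.sqrt(2.0 / np.pi)
        inner = c * (self.data + 0.044715 * self.data ** 3)
        t = np.tanh(inner)
        out_data = 0.5 * self.data * (1.0 + t)

        def backward(g):
            if self.requires_grad:
                dt = (1.0 - t ** 2) * c * (1.0 + 3 * 0.044715 * self.data ** 2)
                self._accum(g * (0.5 * (1.0 + t) + 0.5 * self.data * dt))

        return self._make(out_data, (self,), backward)

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(self.data[idx], (self,), backward)

    # -- neural-network primitives -------------------------------------------
    def gather_rows(self, indices: np.ndarray):
        """Embedding lookup: self is (K, d), indices any int shape -> (*idx, d)."""
        indices = np.asarray(indices)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, indices.reshape(-1), g.reshape(-1, self.data.shape[-1]))
                self._accum(full)

        return self._make(self.data[indices], (self,), backward)

    def log_softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        z = self.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        sm = np.exp(out_data)

        def backward(g):
            if self.requires_grad:
                self._accum(g - sm * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), backward)

    def softmax(self, axis=-1):
        return self.log_softmax(axis=axis).exp()

    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """1-D convolution. self: (B, Cin, L); weight: (Cout, Cin, k)."""
        x = self.data
        Cout, Cin, k = weight.data.shape
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
        B, _, Lp = x.shape
        Lout = (Lp - k) // stride + 1
        # im2col view: (B, Cin, Lout, k)
        s = x.strides
        col = np.lib.stride_tricks.as_strided(
            x, shape=(B, Cin, Lout, k), strides=(s[0], s[1], s[2] * stride, s[2]),
            writeable=False)
        col2 = col.transpose(0, 2, 1, 3).reshape(B, Lout, Cin * k)
        w2 = weight.data.reshape(Cout, Cin * k)
        out_data = np.einsum("blc,oc->bol", col2, w2, optimize=True)
        if bias is not None:
            out_data = out_data + bias.data[None, :, None]

        def backward(g):
            # g: (B, Cout, Lout)
            if weight.requires_grad:
                gw = np.einsum("bol,blc->oc", g, col2, optimize=True)
                weight._accum(gw.reshape(Cout, Cin, k))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if self.requires_grad:
                gcol = np.einsum("bol,oc->blc", g, w2, optimize=True)
                gcol = gcol.reshape(B, Lout, Cin, k).transpose(0, 2, 1, 3)
                gx = np.zeros((B, Cin, Lp))
                for j in range(k):
                    np.add.at(gx, (slice(None), slice(None),
                                   slice(j, j + Lout * stride, stride)),
                              gcol[:, :, :, j])
                if padding:
                    gx = gx[:, :, padding:Lp - padding]
                self._accum(gx)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out_data, parents, backward)

    def upsample_nearest(self, factor: int):
        """Repeat each position `factor` times along the last axis."""
        def backward(g):
            if self.requires_grad:
                gg = g.reshape(*self.data.shape[:-1], self.data.shape[-1], factor)
                self._accum(gg.sum(axis=-1))

        return self._make(np.repeat(self.data, factor, axis=-1), (self,), backward)

    def overlap_add(self, hop: int, out_len: int):
        """Overlap-add frames. self: (..., T, win) -> (..., out_len)."""
        *lead, T, win = self.data.shape
        out_data = np.zeros((*lead, out_len))
        for t in range(T):
            out_data[..., t * hop:t * hop + win] += self.data[..., t, :]

        def backward(g):
            if self.requires_grad:
                gf = np.empty_like(self.data)
                for t in range(T):
                    gf[..., t, :] = g[..., t * hop:t * hop + win]
                self._accum(gf)

        return self._make(out_data, (self,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])

        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        sh = list(t.data.shape)
        sh.insert(axis if axis >= 0 else t.data.ndim + 1 + axis, 1)
        expanded.append(t.reshape(*sh))
    return concat(expanded, axis=axis)
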