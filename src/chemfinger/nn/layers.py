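"""Neural building blocks over the autodiff engine.

Initialisation draws from a caller-supplied `numpy.random.Generator`, so
every model in the package is bit-reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data = np.asarray(a, dtype=np.float64).reshape(p.data.shape)

    def state_hash(self) -> str:
        """Digest of all parameters; used to assert freezing contracts."""
        import hashlib

        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = Tensor(_kaiming(rng, (d_in, d_out), d_in), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None):
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.weight = Tensor(_kaiming(rng, (c_out, c_in, kernel), c_in * kernel),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator, scale: float = 0.02):
        self.weight = Tensor(rng.normal(0.0, scale, size=(n, d)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight.gather_rows(idx)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Bidirectional (unmasked) self-attention over (B, S, d)."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError("width must divide by head count")
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.qkv = Linear(d, 3 * d, rng)
        self.proj = Linear(d, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, S, d = x.shape
        h, dh = self.n_heads, self.d_head
        qkv = self.qkv(x)  # (B, S, 3d)
        qkv = qkv.reshape(B, S, 3, h, dh).transpose(2, 0, 3, 1, 4)  # (3,B,h,S,dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = (q @ k.transpose(0, 1, 3, 2)) * (dh ** -0.5)  # (B,h,S,S)
        att = att.softmax(axis=-1)
        out = att @ v  # (B,h,S,dh)
        out = out.transpose(0, 2, 1, 3).reshape(B, S, d)
        return self.proj(out)


class TransformerBlock(Module):
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 mlp_ratio: int = 4):
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, n_heads, rng)
        self.ln2 = LayerNorm(d)
        self.fc1 = Linear(d, mlp_ratio * d, rng)
        self.fc2 = Linear(mlp_ratio * d, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        x = x + self.fc2(self.fc1(self.ln2(x)).gelu())
        return x


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood; logits (N, C), targets (N,) int."""
    logp = logits.log_softmax(axis=-1)
    n = logits.shape[0]
    picked = logp[np.arange(n), np.asarray(targets)]
    return -picked.mean()
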