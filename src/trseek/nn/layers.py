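"""Neural-network building blocks on the autodiff engine: linear, 1D
convolution, layer normalization, multi-head self-attention, transformer
encoder layers, and an Adam optimizer.

Parameter initialization is Glorot-uniform from a caller-supplied
``numpy.random.Generator`` so that two builds with the same seed are
bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, no_grad


class Module:
    """Base class: tracks parameters, train/eval mode, and submodules."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self) -> None:
        self.training = True
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train()

    def eval(self) -> None:
        self.training = False
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.eval()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.eval()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> Tensor:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int) -> None:
        super().__init__()
        self.weight = _glorot(rng, d_in, d_out, (d_in, d_out))
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Valid (no padding) 1D convolution via unfold + matmul."""

    def __init__(
        self,
        rng: np.random.Generator,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
    ) -> None:
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.c_in = c_in
        self.c_out = c_out
        fan_in = c_in * kernel
        self.weight = _glorot(rng, fan_in, c_out, (fan_in, c_out))
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def out_length(self, length: int) -> int:
        return (length - self.kernel) // self.stride + 1

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, C_in, L) -> (B, C_out, T)
        cols = x.unfold1d(self.kernel, self.stride)  # (B, T, C_in*K)
        out = cols @ self.weight + self.bias  # (B, T, C_out)
        return out.transpose(0, 2, 1)


class Dropout(Module):
    def __init__(self, rng: np.random.Generator, p: float) -> None:
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Scaled dot-product self-attention with ``n_heads`` heads."""

    def __init__(self, rng: np.random.Generator, embed_dim: int, n_heads: int) -> None:
        super().__init__()
        if embed_dim % n_heads != 0:
            raise ValueError(f"embed_dim {embed_dim} not divisible by n_heads {n_heads}")
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.d_head = embed_dim // n_heads
        self.wq = Linear(rng, embed_dim, embed_dim)
        self.wk = Linear(rng, embed_dim, embed_dim)
        self.wv = Linear(rng, embed_dim, embed_dim)
        self.wo = Linear(rng, embed_dim, embed_dim)

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        # (B, T, E) -> (B, H, T, Dh)
        return x.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        q = self._split(self.wq(x), B, T)
        k = self._split(self.wk(x), B, T)
        v = self._split(self.wv(x), B, T)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        ctx = attn @ v  # (B, H, T, Dh)
        merged = ctx.transpose(0, 2, 1, 3).reshape(B, T, self.embed_dim)
        return self.wo(merged)


class TransformerEncoderLayer(Module):
    """Pre-norm transformer encoder block with residual connections."""

    def __init__(
        self,
        rng: np.random.Generator,
        embed_dim: int,
        n_heads: int,
        ff_dim: int,
        dropout: float = 0.0,
    ) -> None:
        super().__init__()
        self.attn = MultiHeadAttention(rng, embed_dim, n_heads)
        self.norm1 = LayerNorm(embed_dim)
        self.norm2 = LayerNorm(embed_dim)
        self.ff1 = Linear(rng, embed_dim, ff_dim)
        self.ff2 = Linear(rng, ff_dim, embed_dim)
        self.drop = Dropout(rng, dropout)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.drop(self.attn(self.norm1(x)))
        x = x + self.drop(self.ff2(self.drop(self.ff1(self.norm2(x)).gelu())))
        return x


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            p.data -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
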