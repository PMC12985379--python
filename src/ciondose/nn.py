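"""Neural-network building blocks for the dose and alpha/beta models.

Layers are thin containers of :class:`~ciondose.autodiff.Tensor` parameters;
stochastic layers (dropout) draw from an explicitly threaded numpy
Generator so every forward pass is reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, unfold2d, upsample2x


class Module:
    """Base class: parameter discovery by attribute walking."""

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

        walk(self)
        return params

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("parameter shape mismatch")
            p.data[...] = s


def _init(rng: np.random.Generator, *shape, fan_in: int | None = None) -> Tensor:
    fan = fan_in if fan_in is not None else shape[0]
    scale = 1.0 / np.sqrt(max(fan, 1))
    return Tensor(rng.uniform(-scale, scale, shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = _init(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    """2D convolution on (B, H, W, C) tensors via patch extraction."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator):
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.w = _init(rng, kernel * kernel * c_in, c_out,
                       fan_in=kernel * kernel * c_in)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        patches = unfold2d(x, self.kernel, self.stride, self.padding)
        return patches @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        return xn * self.gamma + self.beta


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rate is 0 or no rng is given."""
    if rate <= 0.0 or rng is None:
        return x
    if not (0.0 <= rate < 1.0):
        raise ValueError("dropout rate must be in [0, 1)")
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)


class MultiHeadAttention(Module):
    """Scaled dot-product attention; self- or cross-attention.

    Queries come from ``x``; keys/values from ``context`` (defaults to
    ``x``). With ``causal=True`` token t may only attend to tokens <= t.
    """

    def __init__(self, embed_dim: int, n_heads: int, rng: np.random.Generator,
                 causal: bool = False):
        if embed_dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = embed_dim // n_heads
        self.causal = causal
        self.wq = Linear(embed_dim, embed_dim, rng)
        self.wk = Linear(embed_dim, embed_dim, rng)
        self.wv = Linear(embed_dim, embed_dim, rng)
        self.wo = Linear(embed_dim, embed_dim, rng)

    def __call__(self, x: Tensor, context: Tensor | None = None) -> Tensor:
        ctx = x if context is None else context
        B, T, E = x.shape
        S = ctx.shape[1]
        h, d = self.n_heads, self.d_head

        def split(t: Tensor, L: int) -> Tensor:
            return t.reshape(B, L, h, d).transpose(0, 2, 1, 3)  # (B,h,L,d)

        q = split(self.wq(x), T)
        k = split(self.wk(ctx), S)
        v = split(self.wv(ctx), S)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        if self.causal:
            if T != S:
                raise ValueError("causal attention requires matching lengths")
            bias = np.triu(np.full((T, T), -1e30), k=1)
            scores = scores + Tensor(bias)
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, E)
        return self.wo(out)


class TransformerBlock(Module):
    """Pre-norm transformer block with dropout after attention and MLP."""

    def __init__(self, embed_dim: int, n_heads: int, mlp_ratio: int,
                 rng: np.random.Generator, causal: bool = False,
                 cross: bool = False):
        self.attn = MultiHeadAttention(embed_dim, n_heads, rng, causal=causal)
        self.ln1 = LayerNorm(embed_dim)
        self.ln2 = LayerNorm(embed_dim)
        self.ln_ctx = LayerNorm(embed_dim) if cross else None
        hidden = embed_dim * mlp_ratio
        self.fc1 = Linear(embed_dim, hidden, rng)
        self.fc2 = Linear(hidden, embed_dim, rng)

    def __call__(self, x: Tensor, rate: float = 0.0,
                 rng: np.random.Generator | None = None,
                 context: Tensor | None = None) -> Tensor:
        ctx = self.ln_ctx(context) if context is not None else None
        x = x + dropout(self.attn(self.ln1(x), context=ctx), rate, rng)
        x = x + dropout(self.fc2(self.fc1(self.ln2(x)).gelu()), rate, rng)
        return x


class SliceEncoder(Module):
    """Convolutional encoder turning one 2D slice into one token.

    Two stride-2 convolutions (H,W -> H/4,W/4) followed by a linear map to
    the embedding dimension. Applied to all depth slices of a batch at once.
    """

    def __init__(self, hw: tuple[int, int], c_in: int, channels: int,
                 embed_dim: int, rng: np.random.Generator):
        H, W = hw
        if H % 4 or W % 4:
            raise ValueError("lateral grid must be divisible by 4")
        self.conv1 = Conv2d(c_in, channels, 3, 2, 1, rng)
        self.conv2 = Conv2d(channels, channels, 3, 2, 1, rng)
        self.flat_dim = (H // 4) * (W // 4) * channels
        self.proj = Linear(self.flat_dim, embed_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B = x.shape[0]
        x = self.conv1(x).relu()
        x = self.conv2(x).relu()
        return self.proj(x.reshape(B, self.flat_dim))


class SliceDecoder(Module):
    """Token -> 2D slice decoder.

    A two-layer MLP expands each depth token into its full 2D output slice.
    The dense output layer mixes the whole lateral plane at once, so no
    upsampling convolutions (and none of their large patch intermediates)
    are needed; this keeps the decoder memory traffic proportional to the
    output size.
    """

    def __init__(self, hw: tuple[int, int], channels: int, embed_dim: int,
                 rng: np.random.Generator):
        H, W = hw
        self.hw = (H, W)
        hidden = 2 * embed_dim
        self.fc1 = Linear(embed_dim, hidden, rng)
        self.fc2 = Linear(hidden, H * W, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B = x.shape[0]
        H, W = self.hw
        x = self.fc2(self.fc1(x).relu())
        return x.reshape(B, H, W, 1)


class Adam:
    """Adam with per-phase re-initializable learning rate."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


__all__ = [
    "Module", "Linear", "Conv2d", "LayerNorm", "MultiHeadAttention",
    "TransformerBlock", "SliceEncoder", "SliceDecoder", "Adam",
    "dropout", "concat",
]
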