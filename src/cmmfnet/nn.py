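"""Neural-network layers and the Adam optimizer on top of :mod:`cmmfnet._tensor`.

The layer set is deliberately small: linear maps, layer normalization,
multi-head self-attention and the pre-norm transformer block used by both
the CT encoders and the fusion stage.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, layer_norm


def trunc_normal(rng: np.random.Generator, shape, sd: float = 0.02) -> np.ndarray:
    """Truncated normal at +-2 sd, the usual ViT embedding initializer."""
    x = rng.normal(0.0, sd, size=shape)
    bad = np.abs(x) > 2.0 * sd
    while bad.any():
        x[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(x) > 2.0 * sd
    return x


class Module:
    """Base class with recursive named-parameter collection."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
                isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for k, p in self._params.items():
            out[prefix + k] = p
        for k, m in self._modules.items():
            out.update(m.named_parameters(prefix + k + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    """y = x @ W + b with fan-in scaled uniform initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = 1.0 / np.sqrt(in_dim)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(in_dim, out_dim)),
                             requires_grad=True)
        self.bias = (Tensor(rng.uniform(-bound, bound, size=(out_dim,)),
                            requires_grad=True) if bias else None)
        self.in_dim, self.out_dim = in_dim, out_dim

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, affine: bool = True, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        if affine:
            self.gain = Tensor(np.ones(dim), requires_grad=True)
            self.shift = Tensor(np.zeros(dim), requires_grad=True)
        else:
            self.gain = None
            self.shift = None

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, eps=self.eps, gain=self.gain, bias=self.shift)


class MultiHeadSelfAttention(Module):
    """softmax(Q K^T / sqrt(d_k)) V over the token axis, m parallel heads."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError(f"embed dim {dim} not divisible by {n_heads} heads")
        self.dim, self.n_heads = dim, n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        m, hd = self.n_heads, self.head_dim

        def split(z: Tensor) -> Tensor:  # (B,T,D) -> (B,m,T,hd)
            return z.reshape(b, t, m, hd).transpose((0, 2, 1, 3))

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(hd))
        attn = scores.softmax(axis=-1)
        ctx = attn @ v                                   # (B,m,T,hd)
        ctx = ctx.transpose((0, 2, 1, 3)).reshape(b, t, d)
        return self.wo(ctx)

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Row-stochastic attention maps, (B, heads, T, T); inspection only."""
        b, t, _ = x.shape
        m, hd = self.n_heads, self.head_dim
        q = self.wq(x).data.reshape(b, t, m, hd).transpose(0, 2, 1, 3)
        k = self.wk(x).data.reshape(b, t, m, hd).transpose(0, 2, 1, 3)
        s = q @ np.swapaxes(k, -1, -2) / np.sqrt(hd)
        s -= s.max(axis=-1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=-1, keepdims=True)


class TransformerBlock(Module):
    """Pre-norm block: x + MHSA(LN(x)), then optionally x + MLP(LN(x)).

    With the attention output projection and the MLP output projection both
    zeroed the block is the identity map (pure residual path).
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 mlp_ratio: float = 4.0, ffn: bool = True):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ffn = ffn
        if ffn:
            hidden = int(round(mlp_ratio * dim))
            self.ln2 = LayerNorm(dim)
            self.fc1 = Linear(dim, hidden, rng)
            self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        if self.ffn:
            x = x + self.fc2(self.fc1(self.ln2(x)).gelu())
        return x


class Adam:
    """Adam with L2 weight decay folded into the gradient (classic form)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.99),
                 weight_decay: float = 1e-3, eps: float = 1e-8):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            mhat = self._m[k] / (1 - b1 ** self.t)
            vhat = self._v[k] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
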