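"""Neural-network building blocks on top of the autograd tensor.

Initialisation draws from a caller-supplied ``numpy.random.Generator`` so a
model is fully determined by its seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concatenate, softmax


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            obj = stack.pop()
            for value in vars(obj).values():
                if isinstance(value, Tensor) and value.requires_grad:
                    if id(value) not in seen:
                        seen.add(id(value))
                        params.append(value)
                elif isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    stack.extend(v for v in value if isinstance(v, Module))
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state length mismatch")
        for p, s in zip(params, state):
            p.data = s.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(1.0 / d_in)
        self.weight = Tensor(rng.uniform(-scale, scale, (d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        xhat = centred / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; a no-op unless ``training`` is set."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = float(p)
        self.rng = rng
        self.training = False

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(z: Tensor) -> Tensor:  # (b, t, d) -> (b, h, t, dh)
            return z.reshape(b, t, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.wo(ctx)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder layer: attention and GELU-free (ReLU) feed-forward."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 dropout: float, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.drop(self.attn(self.ln1(x)))
        x = x + self.drop(self.ff2(self.ff1(self.ln2(x)).relu()))
        return x


class TransformerEncoder(Module):
    def __init__(self, n_layers: int, d_model: int, n_heads: int, d_ff: int,
                 dropout: float, rng: np.random.Generator):
        self.layers = [
            TransformerEncoderLayer(d_model, n_heads, d_ff, dropout, rng)
            for _ in range(n_layers)
        ]
        self.ln_out = LayerNorm(d_model)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return self.ln_out(x)

    def set_training(self, flag: bool) -> None:
        for layer in self.layers:
            layer.drop.training = flag


class LSTM(Module):
    """Single-layer LSTM unrolled over the time axis of (B, T, D) input."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        self.wx = Linear(d_in, 4 * d_hidden, rng)
        self.wh = Linear(d_hidden, 4 * d_hidden, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        dh = self.d_hidden
        h = Tensor(np.zeros((b, dh)))
        c = Tensor(np.zeros((b, dh)))
        for step in range(t):
            xt = x[:, step, :]
            gates = self.wx(xt) + self.wh(h)
            i = gates[:, :dh].sigmoid()
            f = gates[:, dh:2 * dh].sigmoid()
            g = gates[:, 2 * dh:3 * dh].tanh()
            o = gates[:, 3 * dh:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h  # final hidden state


class MLP(Module):
    """Fully connected stack with ReLU between layers (linear final layer)."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


def mse_loss(pred: Tensor, target: np.ndarray | Tensor) -> Tensor:
    target = Tensor.as_tensor(target)
    diff = pred - target
    return (diff * diff).mean()


__all__ = [
    "Module", "Linear", "LayerNorm", "Dropout", "MultiHeadSelfAttention",
    "TransformerEncoderLayer", "TransformerEncoder", "LSTM", "MLP",
    "mse_loss", "concatenate",
]
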