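"""Neural-network layers used by the TCN autoencoder and the link predictor.

Thin layer objects over :mod:`grnlink._autograd`: each holds its
:class:`~grnlink._autograd.Parameter` tensors and a ``__call__`` building the
forward graph.  Initialization is fan-in-scaled uniform, drawn from the
``numpy.random.Generator`` passed at construction so that a model built from a
seed is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Parameter, Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv1dCausal",
    "Dropout",
    "LayerNorm",
    "FeedForward",
    "MultiheadSelfAttention",
]


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _submodules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                yield from (item for item in value if isinstance(item, Module))

    def train(self):
        self.training = True
        for m in self._submodules():
            m.train()
        return self

    def eval(self):
        self.training = False
        for m in self._submodules():
            m.eval()
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}

        def visit(mod: "Module", prefix: str):
            for name, value in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Parameter):
                    state[key] = value.data.copy()
                elif isinstance(value, Module):
                    visit(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")

        visit(self, "")
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        def visit(mod: "Module", prefix: str):
            for name, value in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Parameter):
                    value.data = np.asarray(state[key], dtype=np.float64).copy()
                elif isinstance(value, Module):
                    visit(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")

        visit(self, "")
        return self


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_fan_in_uniform(rng, (in_features, out_features), in_features))
        self.bias = Parameter(_fan_in_uniform(rng, (out_features,), in_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1dCausal(Module):
    """Dilated causal 1-D convolution, output length == input length."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int, rng: np.random.Generator):
        super().__init__()
        if kernel_size < 1:
            raise ValueError(f"kernel_size must be >= 1, got {kernel_size}")
        if dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {dilation}")
        fan_in = in_channels * kernel_size
        self.weight = Parameter(
            _fan_in_uniform(rng, (out_channels, in_channels, kernel_size), fan_in)
        )
        self.bias = Parameter(_fan_in_uniform(rng, (out_channels,), fan_in))
        self.dilation = int(dilation)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d_causal(self.weight, self.bias, self.dilation)


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Mask drawn from ``rng``."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LayerNorm(Module):
    """Normalize over the last axis; learnable affine (gamma, beta)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


class FeedForward(Module):
    """Two-layer position-wise MLP with ReLU, as in a Transformer block."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class MultiheadSelfAttention(Module):
    """Multi-head scaled dot-product self-attention over a set of tokens.

    Input ``(n_tokens, dim)``; query = key = value.  No positional encoding:
    genes form an unordered set, so the layer is permutation-equivariant.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError(f"hidden dim {dim} not divisible by n_heads {n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self._last_attn: np.ndarray | None = None  # (n_heads, n, n), for inspection

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        h, d = self.n_heads, self.head_dim

        def split_heads(t: Tensor) -> Tensor:
            # (n, dim) -> (h, n, d)
            return t.reshape(n, h, d).swapaxes(0, 1)

        q = split_heads(self.wq(x))
        k = split_heads(self.wk(x))
        v = split_heads(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))
        attn = scores.softmax(axis=-1)
        self._last_attn = attn.data
        out = attn @ v  # (h, n, d)
        merged = out.swapaxes(0, 1).reshape(n, self.dim)
        return self.wo(merged)
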