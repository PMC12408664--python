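"""Neural-network building blocks: layers, dropout, and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, relu

__all__ = ["Linear", "MLP", "Adam", "dropout_mask"]


class Linear:
    """Dense layer y = xW + b with Glorot-uniform initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        self.W = Tensor(rng.uniform(-limit, limit, size=(in_dim, out_dim)), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None
        self.in_dim, self.out_dim = in_dim, out_dim

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    @property
    def parameters(self) -> list[Tensor]:
        return [self.W] + ([self.b] if self.b is not None else [])


def dropout_mask(shape: tuple[int, ...], rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted-dropout mask (training only); multiply activations by it."""
    keep = 1.0 - rate
    return Tensor(rng.binomial(1, keep, size=shape) / keep)


class MLP:
    """Stack of Linear layers with ReLU hidden activations.

    ``dims`` is [in, h1, ..., out]. The output layer is linear; callers apply
    their own output nonlinearity. Dropout (if any) follows each hidden ReLU
    and is active only when a training rng is passed to ``__call__``.
    """

    def __init__(self, dims: list[int], rng: np.random.Generator, dropout: float = 0.0):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.dropout = float(dropout)

    def __call__(self, x: Tensor, train_rng: np.random.Generator | None = None) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = relu(x)
                if self.dropout > 0 and train_rng is not None:
                    x = x * dropout_mask(x.shape, self.dropout, train_rng)
        return x

    @property
    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters]


class Adam:
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
            p.zero_grad()

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
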