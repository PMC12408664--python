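"""Multi-head self-attention predictor over DAE latent embeddings.

Each sample's bottleneck vector is reshaped into ``n_tokens`` tokens of width
``token_dim``; per head i the tokens are projected to queries, keys and values
(Q_i = X W_i^Q, etc.), scaled dot-product attention softmax(QKᵀ/√d_k)V is
applied, head outputs are concatenated and mixed by W^O, and the flattened
result feeds a fully connected MLP ending in a single sigmoid unit — the
predicted probability that the sample is drug-sensitive. With ``n_heads = 0``
the attention block is bypassed and the predictor is a plain MLP, which is the
zero-head arm of the head-count sweep. No positional encoding is used: latent
features carry no order, and the attention output is equivariant to token
permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concatenate, sigmoid, softmax
from .nn import MLP, dropout_mask

__all__ = [
    "AttentionConfig",
    "PredictorModel",
    "scaled_dot_attention",
    "multi_head_attention",
    "predict_proba",
    "classification_loss",
]

EPS = 1e-7


@dataclass
class AttentionConfig:
    n_heads: int = 8
    n_tokens: int = 8
    token_dim: int = 64
    predictor_dims: list[int] = field(default_factory=lambda: [128, 64])
    dropout: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_heads < 0:
            raise ValueError("n_heads must be ≥ 0")
        if self.n_tokens < 1 or self.token_dim < 1:
            raise ValueError("n_tokens and token_dim must be ≥ 1")
        if self.n_heads > 0:
            if self.token_dim % self.n_heads != 0:
                raise ValueError(
                    f"token_dim {self.token_dim} not divisible by n_heads {self.n_heads}"
                )
            if self.token_dim // self.n_heads < 1:
                raise ValueError("per-head key dimension d_k must be ≥ 1")

    @property
    def bottleneck(self) -> int:
        return self.n_tokens * self.token_dim

    @property
    def d_k(self) -> int:
        return self.token_dim // self.n_heads if self.n_heads > 0 else self.token_dim


class PredictorModel:
    """Per-head Q/K/V projections, output mixing W^O, and the MLP head."""

    def __init__(self, config: AttentionConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, dk = config.token_dim, config.d_k

        def proj(rows, cols):
            limit = np.sqrt(6.0 / (rows + cols))
            return Tensor(rng.uniform(-limit, limit, size=(rows, cols)), requires_grad=True)

        self.Wq = [proj(d, dk) for _ in range(config.n_heads)]
        self.Wk = [proj(d, dk) for _ in range(config.n_heads)]
        self.Wv = [proj(d, dk) for _ in range(config.n_heads)]
        self.Wo = proj(d, d) if config.n_heads > 0 else None
        self.mlp = MLP(
            [config.bottleneck, *config.predictor_dims, 1], rng, dropout=config.dropout
        )

    @property
    def parameters(self) -> list[Tensor]:
        params = [*self.Wq, *self.Wk, *self.Wv]
        if self.Wo is not None:
            params.append(self.Wo)
        return params + self.mlp.parameters

    # -- differentiable forward ----------------------------------------------
    def attend(self, tokens: Tensor) -> Tensor:
        """Multi-head attention over tokens of shape (..., n_tokens, token_dim)."""
        if self.config.n_heads == 0:
            return tokens
        heads = []
        for Wq, Wk, Wv in zip(self.Wq, self.Wk, self.Wv):
            heads.append(_attend_tensor(tokens @ Wq, tokens @ Wk, tokens @ Wv))
        return concatenate(heads, axis=-1) @ self.Wo

    def forward(self, Z: Tensor, train_rng: np.random.Generator | None = None) -> Tensor:
        """Latent matrix (n, bottleneck) → sensitivity probabilities (n,)."""
        cfg = self.config
        if Z.shape[-1] != cfg.bottleneck:
            raise ValueError(f"latent width {Z.shape[-1]} != n_tokens·token_dim {cfg.bottleneck}")
        n = Z.shape[0]
        tokens = Z.reshape(n, cfg.n_tokens, cfg.token_dim)
        attended = self.attend(tokens)
        flat = attended.reshape(n, cfg.bottleneck)
        if cfg.dropout > 0 and train_rng is not None:
            flat = flat * dropout_mask(flat.shape, cfg.dropout, train_rng)
        logits = self.mlp(flat, train_rng=train_rng)
        return sigmoid(logits.reshape(n))


def _attend_tensor(Q: Tensor, K: Tensor, V: Tensor) -> Tensor:
    d_k = Q.shape[-1]
    weights = softmax((Q @ K.T) * (1.0 / np.sqrt(d_k)), axis=-1)
    return weights @ V


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """softmax(QKᵀ/√d_k)V for plain arrays (batched on leading axes)."""
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("Q and K must share the key dimension d_k")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("K and V must have equally many rows")
    return _attend_tensor(Tensor(Q), Tensor(K), Tensor(V)).numpy()


def multi_head_attention(X_tokens: np.ndarray, model: PredictorModel) -> np.ndarray:
    """Apply the model's attention block to one token matrix (n_tokens × token_dim)."""
    if model.config.n_heads < 1:
        raise ValueError("multi_head_attention requires n_heads ≥ 1")
    X_tokens = np.asarray(X_tokens, dtype=np.float64)
    if X_tokens.shape != (model.config.n_tokens, model.config.token_dim):
        raise ValueError(
            f"expected ({model.config.n_tokens}, {model.config.token_dim}), got {X_tokens.shape}"
        )
    return model.attend(Tensor(X_tokens)).numpy()


def predict_proba(model: PredictorModel, Z: np.ndarray) -> np.ndarray:
    """Per-sample sensitivity probabilities in [0,1] (inference mode)."""
    Z = np.asarray(Z, dtype=np.float64)
    return model.forward(Tensor(Z)).numpy()


def classification_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy with scores clipped to [ε, 1−ε]."""
    scores, labels = np.asarray(scores, dtype=np.float64), np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels length mismatch")
    s = np.clip(scores, EPS, 1 - EPS)
    return float(-np.mean(labels * np.log(s) + (1 - labels) * np.log(1 - s)))


def bce_loss_tensor(scores: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable binary cross-entropy used during training."""
    y = Tensor(np.asarray(labels, dtype=np.float64))
    s = scores.clamp(EPS, 1 - EPS)
    return -(y * s.log() + (1.0 - y) * (1.0 - s).log()).mean()
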