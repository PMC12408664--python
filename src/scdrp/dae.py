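"""Denoising autoencoder (DAE) for expression-feature extraction.

The same architecture serves both domains: random entries of the input are
masked to zero (Bernoulli corruption at ``noise_rate``), an encoder with ReLU
hidden layers maps the corrupted matrix to a low-dimensional bottleneck, and a
mirrored decoder reconstructs the clean input under mean-squared error. The
encoder alone is reused downstream: cleanly (no noise, no dropout) embedding
samples for prediction and alignment.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor
from .datamodel import ExpressionMatrix
from .nn import MLP, Adam

__all__ = [
    "DAEConfig",
    "DAEModel",
    "noise_inject",
    "reconstruction_loss",
    "fit_dae",
    "encode",
    "save_dae",
    "load_dae",
]


@dataclass
class DAEConfig:
    input_dim: int
    encoder_dims: list[int] = field(default_factory=lambda: [256, 128])
    bottleneck: int = 512
    noise_rate: float = 0.2
    dropout: float = 0.3
    epochs: int = 500
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.bottleneck < 1:
            raise ValueError("bottleneck must be ≥ 1")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("noise_rate must lie in [0,1]")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0,1)")
        if self.input_dim < 1 or any(d < 1 for d in self.encoder_dims):
            raise ValueError("all dimensions must be ≥ 1")


class DAEModel:
    """Trained encoder/decoder pair with its config and loss history."""

    def __init__(self, config: DAEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        enc_dims = [config.input_dim, *config.encoder_dims, config.bottleneck]
        dec_dims = [config.bottleneck, *reversed(config.encoder_dims), config.input_dim]
        self.encoder = MLP(enc_dims, rng, dropout=config.dropout)
        self.decoder = MLP(dec_dims, rng, dropout=0.0)
        self.training_history: list[float] = []

    @property
    def parameters(self) -> list[Tensor]:
        return self.encoder.parameters + self.decoder.parameters

    def encode_tensor(self, x: Tensor) -> Tensor:
        """Noise-free, dropout-free encoder forward pass (differentiable)."""
        return self.encoder(x, train_rng=None)


def noise_inject(X: np.ndarray, rate: float, seed: int) -> np.ndarray:
    """Mask each entry to zero independently with probability ``rate``."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("noise rate must lie in [0,1]")
    X = np.asarray(X, dtype=np.float64)
    rng = np.random.default_rng(seed)
    keep = rng.random(X.shape) >= rate
    return X * keep


def reconstruction_loss(X: np.ndarray, X_recon: np.ndarray) -> float:
    """Mean squared error over all matrix entries."""
    X, X_recon = np.asarray(X), np.asarray(X_recon)
    if X.shape != X_recon.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_recon.shape}")
    return float(np.mean((X - X_recon) ** 2))


def fit_dae(
    X: ExpressionMatrix | np.ndarray, config: DAEConfig, init_from: DAEModel | None = None
) -> DAEModel:
    """Train a DAE to reconstruct ``X`` from its noise-corrupted version.

    Full-batch Adam for ``config.epochs`` epochs with a fresh corruption mask
    each epoch. Deterministic under ``config.seed``. ``init_from`` warm-starts
    the parameters from an already-trained DAE of identical architecture
    (useful to keep two domains' latent spaces in a shared basis).
    """
    data = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=np.float64)
    if not np.isfinite(data).all():
        raise ValueError("input contains non-finite values")
    if data.shape[1] != config.input_dim:
        raise ValueError(f"input has {data.shape[1]} genes, config expects {config.input_dim}")
    model = DAEModel(config)
    if init_from is not None:
        for dst, src in zip(model.parameters, init_from.parameters):
            if dst.data.shape != src.data.shape:
                raise ValueError("init_from model has a different architecture")
            dst.data = src.data.copy()
    opt = Adam(model.parameters, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    clean = Tensor(data)
    for epoch in range(config.epochs):
        mask = rng.random(data.shape) >= config.noise_rate
        noisy = Tensor(data * mask)
        z = model.encoder(noisy, train_rng=rng if config.dropout > 0 else None)
        recon = model.decoder(z)
        loss = ((recon - clean) ** 2).mean()
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"DAE training diverged at epoch {epoch} (lr={config.learning_rate})"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        model.training_history.append(float(loss.data))
    return model


def encode(model: DAEModel, X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Deterministic latent embedding (n_samples × bottleneck) of clean input."""
    data = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] != model.config.input_dim:
        raise ValueError(
            f"expected (n, {model.config.input_dim}) input, got {data.shape}"
        )
    return model.encode_tensor(Tensor(data)).numpy()


def _collect_params(model: DAEModel) -> dict[str, np.ndarray]:
    out = {}
    for tag, mlp in (("enc", model.encoder), ("dec", model.decoder)):
        for i, layer in enumerate(mlp.layers):
            out[f"{tag}_{i}_W"] = layer.W.data
            out[f"{tag}_{i}_b"] = layer.b.data
    return out


def save_dae(model: DAEModel, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    np.savez(os.path.join(directory, "params.npz"), **_collect_params(model))
    with open(os.path.join(directory, "config.json"), "w") as fh:
        json.dump({"dae": asdict(model.config), "history": model.training_history}, fh)


def load_dae(directory: str) -> DAEModel:
    with open(os.path.join(directory, "config.json")) as fh:
        meta = json.load(fh)
    model = DAEModel(DAEConfig(**meta["dae"]))
    model.training_history = list(meta.get("history", []))
    params = np.load(os.path.join(directory, "params.npz"))
    for tag, mlp in (("enc", model.encoder), ("dec", model.decoder)):
        for i, layer in enumerate(mlp.layers):
            layer.W.data = params[f"{tag}_{i}_W"]
            layer.b.data = params[f"{tag}_{i}_b"]
    return model
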