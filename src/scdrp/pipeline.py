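"""Convenience wiring of the full synthetic-to-prediction workflow.

These helpers pick a compact architecture matched to the synthetic data's
scale (a few hundred genes) so the complete pipeline — normalize, balance,
bulk pretrain, joint adaptation, transfer scoring — runs in seconds on one
CPU. The real-data defaults (bottleneck 512, 500 epochs, ...) live in
``scdrp.config``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attention import AttentionConfig
from .dae import DAEConfig
from .datamodel import ExpressionMatrix, ResponseLabels
from .preprocess import balance_classes, normalize_log
from .simulate import SimConfig, simulate_paired
from .transfer import DaNNConfig, MMDConfig, TransferResult, fit_transfer

__all__ = ["SmallModelSpec", "run_transfer_pipeline", "run_synthetic_pipeline"]


@dataclass
class SmallModelSpec:
    """Architecture sized for simulated data (hundreds of genes/cells)."""

    bottleneck: int = 32
    encoder_dims: list[int] = field(default_factory=lambda: [64])
    n_tokens: int = 4
    n_heads: int = 4
    predictor_dims: list[int] = field(default_factory=lambda: [32, 16])
    dropout: float = 0.1
    noise_rate: float = 0.2
    dae_epochs: int = 150
    dann_epochs: int = 40
    pretrain_epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-3
    warm_start: bool = True  # share the latent basis between the two DAEs


def run_transfer_pipeline(
    bulk: ExpressionMatrix,
    y_bulk: ResponseLabels,
    sc_counts: ExpressionMatrix,
    seed: int = 0,
    omega: float = 0.25,
    theta: float = 0.1,
    balance: str = "none",
    spec: SmallModelSpec | None = None,
) -> TransferResult:
    """Normalize single-cell counts, optionally balance bulk classes, and run
    the three-stage transfer training."""
    spec = spec or SmallModelSpec()
    sc = normalize_log(sc_counts) if sc_counts.layer == "counts" else sc_counts
    if balance != "none":
        bulk, y_bulk = balance_classes(bulk, y_bulk, method=balance, seed=seed)
    n_genes = len([g for g in bulk.gene_ids if g in set(sc.gene_ids)])
    dae_kwargs = dict(
        input_dim=n_genes,
        encoder_dims=list(spec.encoder_dims),
        bottleneck=spec.bottleneck,
        noise_rate=spec.noise_rate,
        dropout=spec.dropout,
        epochs=spec.dae_epochs,
        learning_rate=spec.learning_rate,
    )
    dae_bulk = DAEConfig(seed=seed, **dae_kwargs)
    dae_sc = DAEConfig(seed=seed + 1, **dae_kwargs)
    pred = AttentionConfig(
        n_heads=spec.n_heads,
        n_tokens=spec.n_tokens,
        token_dim=spec.bottleneck // spec.n_tokens,
        predictor_dims=list(spec.predictor_dims),
        dropout=spec.dropout,
        seed=seed,
    )
    dann = DaNNConfig(
        omega=omega,
        theta=theta,
        epochs=spec.dann_epochs,
        batch_size=spec.batch_size,
        learning_rate=spec.learning_rate,
        seed=seed,
        pretrain_epochs=spec.pretrain_epochs,
    )
    return fit_transfer(
        (bulk, y_bulk), sc, dae_bulk, dae_sc, pred, dann, warm_start=spec.warm_start
    )


def run_synthetic_pipeline(
    sim: SimConfig,
    seed: int | None = None,
    omega: float = 0.25,
    theta: float = 0.1,
    balance: str = "none",
    spec: SmallModelSpec | None = None,
):
    """Simulate a paired dataset and run the full pipeline on it.

    Returns ``(result, sc_truth_labels, truth)`` so callers can evaluate the
    transferred scores against the planted ground truth.
    """
    (bulk, y_bulk), (sc, y_sc), truth = simulate_paired(sim)
    seed = sim.seed if seed is None else seed
    result = run_transfer_pipeline(
        bulk, y_bulk, sc, seed=seed, omega=omega, theta=theta, balance=balance, spec=spec
    )
    return result, y_sc, truth
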