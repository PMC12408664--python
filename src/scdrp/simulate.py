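"""Synthetic paired bulk/single-cell data with a planted sensitivity axis.

The generator emulates the statistical structure the transfer method assumes:
two domains (bulk cell lines, single cells) share a linear-Gaussian latent
factor model in which one latent axis drives a binary sensitive/resistant
label. Marker genes load only on that sensitivity axis (positively for
sensitive markers, negatively for resistant markers, magnitude
``effect_size``); all remaining genes load sparsely on the other factors, so
with ``effect_size = 0`` no gene carries label signal. The single-cell domain
additionally receives a per-gene affine distortion (mean offset and scale,
magnitude ``domain_shift``), Poisson count noise, and Bernoulli dropout — the
minimal gap MMD alignment can demonstrably close and the single-cell character
QC/normalization need.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import ExpressionMatrix, ResponseLabels

__all__ = ["SimConfig", "SimTruth", "simulate_paired", "simulate_imbalanced"]


@dataclass
class SimConfig:
    n_genes: int = 300
    n_bulk: int = 400
    n_cells: int = 400
    n_latent: int = 10
    effect_size: float = 3.0
    domain_shift: float = 1.0
    imbalance: float = 0.5  # share of sensitive (label 1) samples
    n_markers_per_class: int = 10
    dropout_rate: float = 0.3
    label_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_bulk", "n_cells", "n_latent", "n_markers_per_class"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        if not (0.0 < self.imbalance < 1.0):
            raise ValueError("imbalance must lie in (0,1)")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0,1)")
        if 2 * self.n_markers_per_class > self.n_genes:
            raise ValueError("too many marker genes for n_genes")
        if min(self.n_bulk, self.n_cells) * min(self.imbalance, 1 - self.imbalance) < 1:
            raise ValueError("imbalance infeasible for the given sample sizes")


@dataclass
class SimTruth:
    bulk_factors: np.ndarray
    sc_factors: np.ndarray
    bulk_labels: np.ndarray
    sc_labels: np.ndarray
    sensitive_markers: list[str] = field(default_factory=list)
    resistant_markers: list[str] = field(default_factory=list)
    shift: np.ndarray | None = None
    scale: np.ndarray | None = None


def _labels_from_axis(
    axis: np.ndarray, imbalance: float, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Threshold the noisy sensitivity axis at the empirical quantile so that
    round(imbalance·n) samples are sensitive."""
    noisy = axis + rng.normal(0, noise_sd, size=axis.shape)
    n_pos = int(round(imbalance * len(axis)))
    n_pos = min(max(n_pos, 1), len(axis) - 1)
    threshold = np.sort(noisy)[len(axis) - n_pos - 1]
    return (noisy > threshold).astype(np.int64)


def simulate_paired(config: SimConfig) -> tuple[
    tuple[ExpressionMatrix, ResponseLabels],
    tuple[ExpressionMatrix, ResponseLabels],
    SimTruth,
]:
    """Generate a paired bulk/single-cell dataset with shared latent structure.

    Returns ``((bulk_X, bulk_y), (sc_X, sc_y), truth)``. Bulk expression is a
    continuous log-scale matrix (layer ``"lognorm"``); single-cell expression
    is a raw count matrix (layer ``"counts"``) ready for QC/normalization.
    """
    rng = np.random.default_rng(config.seed)
    G, K = config.n_genes, config.n_latent
    n_mark = config.n_markers_per_class
    gene_ids = [f"g{i}" for i in range(G)]
    sens_markers = gene_ids[:n_mark]
    res_markers = gene_ids[n_mark : 2 * n_mark]

    # loadings: factor 0 is the sensitivity axis and loads only marker genes
    W = np.zeros((K, G))
    if K > 1:
        mask = rng.random((K - 1, G - 2 * n_mark)) < 0.3
        W[1:, 2 * n_mark :] = rng.normal(0, 1, size=(K - 1, G - 2 * n_mark)) * mask
    W[0, :n_mark] = config.effect_size
    W[0, n_mark : 2 * n_mark] = -config.effect_size

    baseline = rng.uniform(2.0, 6.0, size=G)

    Z_bulk = rng.normal(size=(config.n_bulk, K))
    Z_sc = rng.normal(size=(config.n_cells, K))
    y_bulk = _labels_from_axis(Z_bulk[:, 0], config.imbalance, config.label_noise_sd, rng)
    y_sc = _labels_from_axis(Z_sc[:, 0], config.imbalance, config.label_noise_sd, rng)

    bulk_vals = Z_bulk @ W + baseline + rng.normal(0, 1.0, size=(config.n_bulk, G))
    bulk_vals = np.maximum(bulk_vals, 0.0)

    # single-cell: shared generative law + affine domain distortion + counts
    shift = config.domain_shift * rng.normal(0, 1.0, size=G)
    scale = np.exp(rng.normal(0, 0.1 * config.domain_shift, size=G))
    sc_signal = (Z_sc @ W + baseline) * scale + shift
    mu = np.maximum(sc_signal + rng.normal(0, 0.5, size=(config.n_cells, G)), 0.0)
    sc_counts = rng.poisson(mu).astype(np.float64)
    if config.dropout_rate > 0:
        keep = rng.random(sc_counts.shape) >= config.dropout_rate
        sc_counts *= keep

    bulk_ids = [f"cellline{i}" for i in range(config.n_bulk)]
    sc_ids = [f"cell{i}" for i in range(config.n_cells)]
    bulk = ExpressionMatrix(bulk_vals, bulk_ids, gene_ids, domain="bulk", layer="lognorm")
    sc = ExpressionMatrix(sc_counts, sc_ids, gene_ids, domain="single_cell", layer="counts")
    truth = SimTruth(
        bulk_factors=Z_bulk,
        sc_factors=Z_sc,
        bulk_labels=y_bulk,
        sc_labels=y_sc,
        sensitive_markers=sens_markers,
        resistant_markers=res_markers,
        shift=shift,
        scale=scale,
    )
    return (
        (bulk, ResponseLabels(bulk_ids, y_bulk)),
        (sc, ResponseLabels(sc_ids, y_sc)),
        truth,
    )


def simulate_imbalanced(config: SimConfig | None = None, **overrides):
    """Convenience variant with a 10% minority (sensitive) share."""
    config = config or SimConfig()
    config = replace(config, imbalance=0.1, **overrides)
    return simulate_paired(config)
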