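"""Stage-wise transfer training: bulk pretraining, single-cell DAE fitting,
MMD latent alignment, Louvain-cluster coherence regularization, and final
transfer inference on single cells.

Training proceeds in three stages:

1. **Bulk pretraining** — fit the bulk DAE, then train the attention predictor
   P on clean bulk embeddings E_g(X_g) under binary cross-entropy.
2. **Joint adaptation** — fit the single-cell DAE, cluster the single-cell
   latents once (Louvain on a kNN graph), then jointly minimize

       L = L_class + ω·MMD²(E_g(bulk), E_t(sc)) + θ·R_cluster(E_t(sc))

   over E_g, E_t and P by mini-batch Adam; the decoders stay frozen. The MMD
   term pulls the two latent distributions together in a reproducing-kernel
   Hilbert space; the regularizer keeps each cell's embedding coherent with
   its Louvain cluster centroid (mean of 1 − cosine similarity).
3. **Transfer** — score every single cell with P(E_t(x)), yielding continuous
   sensitivity probabilities in [0,1].
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np
from sklearn.neighbors import kneighbors_graph

from .attention import AttentionConfig, PredictorModel, bce_loss_tensor, predict_proba
from .autodiff import Tensor
from .dae import DAEConfig, DAEModel, encode, fit_dae, load_dae, save_dae
from .datamodel import ExpressionMatrix, ResponseLabels
from .nn import Adam

__all__ = [
    "MMDConfig",
    "DaNNConfig",
    "ModelBundle",
    "PretrainedBulk",
    "TransferResult",
    "mmd",
    "cluster_cells",
    "cluster_regularizer",
    "dann_loss",
    "pretrain_bulk",
    "transfer_adapt",
    "fit_transfer",
    "binarize_scores",
    "align_genes",
    "save_pretrained",
    "load_pretrained",
    "save_bundle",
    "load_bundle",
]


@dataclass
class MMDConfig:
    kernel: str = "rbf_multiscale"
    bandwidths: list[float] | str = "median-heuristic"

    def __post_init__(self):
        if self.kernel not in ("rbf_multiscale", "linear"):
            raise ValueError("kernel must be 'rbf_multiscale' or 'linear'")
        if isinstance(self.bandwidths, list) and any(b <= 0 for b in self.bandwidths):
            raise ValueError("explicit bandwidths must be positive")


@dataclass
class DaNNConfig:
    omega: float = 0.25
    theta: float = 0.1
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 1e-3
    cluster_resolution: float = 1.0
    seed: int = 0
    pretrain_epochs: int | None = None  # predictor pretraining; defaults to `epochs`

    def __post_init__(self):
        if self.omega < 0 or self.theta < 0 or not np.isfinite([self.omega, self.theta]).all():
            raise ValueError("omega and theta must be finite and ≥ 0")


@dataclass
class ModelBundle:
    """All trained components plus their configurations and the seed."""

    bulk_dae: DAEModel
    sc_dae: DAEModel
    predictor: PredictorModel
    gene_ids: list[str]
    dann: DaNNConfig
    mmd_config: MMDConfig = field(default_factory=MMDConfig)


@dataclass
class PretrainedBulk:
    """Stage-1 output: bulk DAE, pretrained predictor, and the training data
    (kept so the joint phase can keep optimizing the class loss)."""

    bulk_dae: DAEModel
    predictor: PredictorModel
    X_bulk: ExpressionMatrix
    y_bulk: ResponseLabels
    dann: DaNNConfig


@dataclass
class TransferResult:
    model: ModelBundle
    loss_trace: list[dict]
    scores: ResponseLabels  # provenance="predicted", continuous scores attached
    clusters: np.ndarray


# -- maximum mean discrepancy -------------------------------------------------

_SCALES = (0.25, 0.5, 1.0, 2.0, 4.0)


def _sq_dists(A: Tensor, B: Tensor) -> Tensor:
    a2 = (A**2).sum(axis=1, keepdims=True)
    b2 = (B**2).sum(axis=1, keepdims=True)
    return (a2 + b2.T - 2.0 * (A @ B.T)).clamp(0.0, np.inf)


def _rbf_bandwidths(X: np.ndarray, Y: np.ndarray, config: MMDConfig) -> np.ndarray:
    if isinstance(config.bandwidths, list):
        return np.asarray(config.bandwidths, dtype=np.float64)
    pooled = np.vstack([X, Y])
    d2 = _sq_dists(Tensor(pooled), Tensor(pooled)).numpy()
    base = np.median(d2[~np.eye(len(pooled), dtype=bool)])
    if base <= 0:
        base = 1.0
    return base * np.asarray(_SCALES)


def _mmd_tensor(Zx: Tensor, Zy: Tensor, config: MMDConfig, bandwidths) -> Tensor:
    """Biased squared-MMD estimate (differentiable)."""
    if config.kernel == "linear":
        diff = Zx.mean(axis=0) - Zy.mean(axis=0)
        return (diff**2).sum()
    total = None
    for bw in bandwidths:
        kxx = ((_sq_dists(Zx, Zx) * (-1.0 / bw)).exp()).mean()
        kyy = ((_sq_dists(Zy, Zy) * (-1.0 / bw)).exp()).mean()
        kxy = ((_sq_dists(Zx, Zy) * (-1.0 / bw)).exp()).mean()
        term = kxx + kyy - 2.0 * kxy
        total = term if total is None else total + term
    return total * (1.0 / len(bandwidths))


def mmd(Z_bulk: np.ndarray, Z_sc: np.ndarray, config: MMDConfig | None = None) -> float:
    """Squared maximum mean discrepancy between two embedding samples.

    ``mean k(x,x') + mean k(y,y') − 2 mean k(x,y)`` with either a linear
    kernel (then equal to ‖mean(X) − mean(Y)‖²) or a multi-scale RBF kernel
    k(x,y) = mean_b exp(−‖x−y‖²/b), bandwidths b from the median heuristic
    (median pooled pairwise squared distance × {0.25, 0.5, 1, 2, 4}).
    """
    config = config or MMDConfig()
    Zx = np.atleast_2d(np.asarray(Z_bulk, dtype=np.float64))
    Zy = np.atleast_2d(np.asarray(Z_sc, dtype=np.float64))
    if Zx.shape[1] != Zy.shape[1]:
        raise ValueError(f"embedding width mismatch: {Zx.shape[1]} vs {Zy.shape[1]}")
    if len(Zx) < 2 or len(Zy) < 2:
        raise ValueError("need at least 2 samples per side")
    bws = _rbf_bandwidths(Zx, Zy, config) if config.kernel == "rbf_multiscale" else None
    return float(_mmd_tensor(Tensor(Zx), Tensor(Zy), config, bws).numpy())


# -- Louvain clustering and the cluster regularizer ---------------------------


def cluster_cells(
    Z_sc: np.ndarray, resolution: float = 1.0, n_neighbors: int = 15, seed: int = 0
) -> np.ndarray:
    """Louvain communities on a symmetrized kNN graph of latent embeddings."""
    Z_sc = np.asarray(Z_sc, dtype=np.float64)
    n = len(Z_sc)
    if n < n_neighbors + 1:
        raise ValueError(f"need ≥ {n_neighbors + 1} cells for {n_neighbors}-NN graph")
    adj = kneighbors_graph(Z_sc, n_neighbors=n_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T)
    G = nx.from_scipy_sparse_array(adj)
    communities = nx.community.louvain_communities(G, resolution=resolution, seed=seed)
    labels = np.empty(n, dtype=np.int64)
    for c, members in enumerate(sorted(communities, key=min)):
        labels[list(members)] = c
    return labels


def _regularizer_tensor(Z: Tensor, clusters: np.ndarray) -> Tensor:
    total = None
    n = Z.shape[0]
    for c in np.unique(clusters):
        idx = np.flatnonzero(clusters == c)
        Zc = Z[idx]
        centroid = Zc.mean(axis=0, keepdims=True)
        dots = (Zc * centroid).sum(axis=1)
        norms = ((Zc**2).sum(axis=1) + 1e-24).sqrt() * ((centroid**2).sum(axis=1) + 1e-24).sqrt()
        contrib = (1.0 - dots / norms).sum()
        total = contrib if total is None else total + contrib
    return total * (1.0 / n)


def cluster_regularizer(Z_sc: np.ndarray, clusters: np.ndarray) -> float:
    """Mean over cells of 1 − cos(cell embedding, its cluster centroid) ∈ [0,2]."""
    Z_sc = np.asarray(Z_sc, dtype=np.float64)
    clusters = np.asarray(clusters)
    if len(Z_sc) != len(clusters):
        raise ValueError("embedding/cluster length mismatch")
    if np.any(np.linalg.norm(Z_sc, axis=1) == 0):
        warnings.warn("zero-norm embedding vector(s): cosine similarity treated as 0")
    return float(_regularizer_tensor(Tensor(Z_sc), clusters).numpy())


def dann_loss(class_loss: float, mmd_value: float, reg_value: float, config: DaNNConfig) -> float:
    """Composite objective: class + ω·MMD + θ·regularizer."""
    return float(class_loss + config.omega * mmd_value + config.theta * reg_value)


def binarize_scores(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Continuous sensitivity scores → binary labels (≥ threshold → sensitive).

    Interpretation-only: the threshold never enters training or the
    threshold-free metrics (AUC, AP).
    """
    return (np.asarray(scores) >= threshold).astype(np.int64)


def align_genes(
    bulk: ExpressionMatrix, sc: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Inner-join the two gene sets (exact id match), keeping bulk order."""
    sc_pos = {g: i for i, g in enumerate(sc.gene_ids)}
    common = [g for g in bulk.gene_ids if g in sc_pos]
    if not common:
        raise ValueError("empty gene intersection between bulk and single-cell matrices")
    bulk_pos = {g: i for i, g in enumerate(bulk.gene_ids)}
    return (
        bulk.subset_genes([bulk_pos[g] for g in common]),
        sc.subset_genes([sc_pos[g] for g in common]),
    )


# -- staged training ----------------------------------------------------------


def pretrain_bulk(
    bulk: tuple[ExpressionMatrix, ResponseLabels],
    dae_bulk: DAEConfig,
    pred: AttentionConfig,
    dann: DaNNConfig,
) -> PretrainedBulk:
    """Stage 1: fit the bulk DAE, then train P on clean bulk embeddings."""
    X_bulk, y_bulk = bulk
    if dae_bulk.input_dim != X_bulk.n_genes:
        raise ValueError(
            f"DAE input_dim {dae_bulk.input_dim} != bulk gene count {X_bulk.n_genes}"
        )
    if pred.bottleneck != dae_bulk.bottleneck:
        raise ValueError("predictor n_tokens·token_dim must equal the DAE bottleneck")
    rng = np.random.default_rng(np.random.SeedSequence([dann.seed, 11]))
    bulk_dae = fit_dae(X_bulk, dae_bulk)
    predictor = PredictorModel(pred)
    Zg = Tensor(encode(bulk_dae, X_bulk))
    y = y_bulk.labels.astype(np.float64)
    opt = Adam(predictor.parameters, lr=dann.learning_rate)
    n_epochs = dann.pretrain_epochs if dann.pretrain_epochs is not None else dann.epochs
    for _ in range(n_epochs):
        loss = bce_loss_tensor(predictor.forward(Zg, train_rng=rng), y)
        opt.zero_grad()
        loss.backward()
        opt.step()
    return PretrainedBulk(bulk_dae, predictor, X_bulk, y_bulk, dann)


def transfer_adapt(
    pre: PretrainedBulk,
    sc: ExpressionMatrix,
    dae_sc: DAEConfig,
    dann: DaNNConfig | None = None,
    mmd_config: MMDConfig | None = None,
    cluster_neighbors: int = 15,
    warm_start: bool = False,
) -> TransferResult:
    """Stages 2–3: single-cell DAE, joint DaNN optimization, transfer scoring.

    ``warm_start`` initializes the single-cell DAE from the trained bulk DAE
    before its reconstruction fitting, so both encoders start in a shared
    latent basis (the MMD term then only has to close the domain gap, not
    resolve an arbitrary rotation between independently trained latents).
    """
    dann = dann or pre.dann
    mmd_config = mmd_config or MMDConfig()
    X_bulk, y_bulk = pre.X_bulk, pre.y_bulk
    if sc.gene_ids != X_bulk.gene_ids:
        _, sc = align_genes(X_bulk, sc)
        if sc.gene_ids != X_bulk.gene_ids:
            raise ValueError("single-cell matrix is missing genes the bulk model was trained on")
    if dae_sc.input_dim != X_bulk.n_genes:
        raise ValueError(f"sc DAE input_dim must equal gene count {X_bulk.n_genes}")
    if dae_sc.bottleneck != pre.bulk_dae.config.bottleneck:
        raise ValueError("bulk and single-cell DAE bottlenecks must match")

    rng = np.random.default_rng(np.random.SeedSequence([dann.seed, 101]))
    bulk_dae, predictor = pre.bulk_dae, pre.predictor
    y = y_bulk.labels.astype(np.float64)

    sc_dae = fit_dae(sc, dae_sc, init_from=pre.bulk_dae if warm_start else None)
    clusters = cluster_cells(
        encode(sc_dae, sc),
        resolution=dann.cluster_resolution,
        n_neighbors=min(cluster_neighbors, sc.n_samples - 1),
        seed=dann.seed,
    )
    joint_params = (
        bulk_dae.encoder.parameters + sc_dae.encoder.parameters + predictor.parameters
    )
    opt = Adam(joint_params, lr=dann.learning_rate)
    bulk_t, sc_t = Tensor(X_bulk.values), Tensor(sc.values)
    n_b, n_s = X_bulk.n_samples, sc.n_samples
    batch = min(dann.batch_size, n_b, n_s)
    steps = max(1, int(np.ceil(n_b / batch)))
    trace: list[dict] = []
    for epoch in range(dann.epochs):
        for _ in range(steps):
            ib = rng.choice(n_b, size=batch, replace=False)
            it = rng.choice(n_s, size=batch, replace=False)
            zb = bulk_dae.encoder(bulk_t[ib], train_rng=None)
            zt = sc_dae.encoder(sc_t[it], train_rng=None)
            class_l = bce_loss_tensor(predictor.forward(zb, train_rng=rng), y[ib])
            bws = (
                _rbf_bandwidths(zb.numpy(), zt.numpy(), mmd_config)
                if mmd_config.kernel == "rbf_multiscale"
                else None
            )
            mmd_l = _mmd_tensor(zb, zt, mmd_config, bws)
            reg_l = _regularizer_tensor(zt, clusters[it])
            total = class_l + dann.omega * mmd_l + dann.theta * reg_l
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"joint training diverged at epoch {epoch}: "
                    f"class={class_l.data:.4g} mmd={mmd_l.data:.4g} reg={reg_l.data:.4g}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            trace.append(
                {
                    "epoch": epoch,
                    "class": float(class_l.data),
                    "mmd": float(mmd_l.data),
                    "regularizer": float(reg_l.data),
                    "total": float(total.data),
                }
            )

    sc_scores = predict_proba(predictor, encode(sc_dae, sc))
    result_labels = ResponseLabels(
        list(sc.sample_ids), binarize_scores(sc_scores), provenance="predicted", scores=sc_scores
    )
    bundle = ModelBundle(
        bulk_dae=bulk_dae,
        sc_dae=sc_dae,
        predictor=predictor,
        gene_ids=list(X_bulk.gene_ids),
        dann=dann,
        mmd_config=mmd_config,
    )
    return TransferResult(model=bundle, loss_trace=trace, scores=result_labels, clusters=clusters)


def fit_transfer(
    bulk: tuple[ExpressionMatrix, ResponseLabels],
    sc: ExpressionMatrix,
    dae_bulk: DAEConfig,
    dae_sc: DAEConfig,
    pred: AttentionConfig,
    dann: DaNNConfig,
    mmd_config: MMDConfig | None = None,
    cluster_neighbors: int = 15,
    warm_start: bool = False,
) -> TransferResult:
    """Run all three training stages end to end and score every single cell.

    Gene sets are inner-joined (bulk order) before any training. The per-step
    loss trace logs class, mmd, regularizer and total components; the logged
    total always equals class + ω·mmd + θ·regularizer.
    """
    X_bulk, y_bulk = bulk
    X_bulk, sc = align_genes(X_bulk, sc)
    pre = pretrain_bulk((X_bulk, y_bulk), dae_bulk, pred, dann)
    return transfer_adapt(
        pre,
        sc,
        dae_sc,
        dann,
        mmd_config=mmd_config,
        cluster_neighbors=cluster_neighbors,
        warm_start=warm_start,
    )


# -- persistence --------------------------------------------------------------


def _save_predictor(pred: PredictorModel, path: str) -> None:
    arrays = {}
    for tag, mats in (("Wq", pred.Wq), ("Wk", pred.Wk), ("Wv", pred.Wv)):
        for i, m in enumerate(mats):
            arrays[f"{tag}_{i}"] = m.data
    if pred.Wo is not None:
        arrays["Wo"] = pred.Wo.data
    for i, layer in enumerate(pred.mlp.layers):
        arrays[f"mlp_{i}_W"] = layer.W.data
        arrays[f"mlp_{i}_b"] = layer.b.data
    np.savez(path, **arrays)


def _load_predictor(config: AttentionConfig, path: str) -> PredictorModel:
    predictor = PredictorModel(config)
    params = np.load(path)
    for tag, mats in (("Wq", predictor.Wq), ("Wk", predictor.Wk), ("Wv", predictor.Wv)):
        for i, m in enumerate(mats):
            m.data = params[f"{tag}_{i}"]
    if predictor.Wo is not None:
        predictor.Wo.data = params["Wo"]
    for i, layer in enumerate(predictor.mlp.layers):
        layer.W.data = params[f"mlp_{i}_W"]
        layer.b.data = params[f"mlp_{i}_b"]
    return predictor


def save_pretrained(pre: PretrainedBulk, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    save_dae(pre.bulk_dae, os.path.join(directory, "bulk_dae"))
    _save_predictor(pre.predictor, os.path.join(directory, "predictor.npz"))
    np.savez(
        os.path.join(directory, "bulk_data.npz"),
        X=pre.X_bulk.values,
        y=pre.y_bulk.labels,
    )
    meta = {
        "stage": "pretrained_bulk",
        "attention": asdict(pre.predictor.config),
        "dann": asdict(pre.dann),
        "gene_ids": pre.X_bulk.gene_ids,
        "sample_ids": pre.X_bulk.sample_ids,
        "layer": pre.X_bulk.layer,
    }
    with open(os.path.join(directory, "bundle.json"), "w") as fh:
        json.dump(meta, fh)


def load_pretrained(directory: str) -> PretrainedBulk:
    meta_path = os.path.join(directory, "bundle.json")
    if not os.path.exists(meta_path):
        raise FileNotFoundError(f"model bundle not found at {directory!r}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    data = np.load(os.path.join(directory, "bulk_data.npz"))
    X_bulk = ExpressionMatrix(
        data["X"], meta["sample_ids"], meta["gene_ids"], domain="bulk", layer=meta["layer"]
    )
    y_bulk = ResponseLabels(meta["sample_ids"], data["y"])
    return PretrainedBulk(
        bulk_dae=load_dae(os.path.join(directory, "bulk_dae")),
        predictor=_load_predictor(
            AttentionConfig(**meta["attention"]), os.path.join(directory, "predictor.npz")
        ),
        X_bulk=X_bulk,
        y_bulk=y_bulk,
        dann=DaNNConfig(**meta["dann"]),
    )


def save_bundle(bundle: ModelBundle, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    save_dae(bundle.bulk_dae, os.path.join(directory, "bulk_dae"))
    save_dae(bundle.sc_dae, os.path.join(directory, "sc_dae"))
    _save_predictor(bundle.predictor, os.path.join(directory, "predictor.npz"))
    meta = {
        "stage": "joint",
        "attention": asdict(bundle.predictor.config),
        "dann": asdict(bundle.dann),
        "mmd": asdict(bundle.mmd_config),
        "gene_ids": bundle.gene_ids,
    }
    with open(os.path.join(directory, "bundle.json"), "w") as fh:
        json.dump(meta, fh)


def load_bundle(directory: str) -> ModelBundle:
    meta_path = os.path.join(directory, "bundle.json")
    if not os.path.exists(meta_path):
        raise FileNotFoundError(f"model bundle not found at {directory!r}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    return ModelBundle(
        bulk_dae=load_dae(os.path.join(directory, "bulk_dae")),
        sc_dae=load_dae(os.path.join(directory, "sc_dae")),
        predictor=_load_predictor(
            AttentionConfig(**meta["attention"]), os.path.join(directory, "predictor.npz")
        ),
        gene_ids=list(meta["gene_ids"]),
        dann=DaNNConfig(**meta["dann"]),
        mmd_config=MMDConfig(**meta["mmd"]),
    )
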