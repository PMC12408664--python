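"""Downstream biology: differential expression between predicted classes,
per-cell gene-set scores, the predicted-vs-true score correlation with its
random-gene-set null, and integrated-gradient key-gene ranking."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .attention import PredictorModel
from .autodiff import Tensor
from .dae import DAEModel
from .datamodel import ExpressionMatrix

__all__ = [
    "GeneSetScore",
    "AttributionResult",
    "find_degs",
    "gene_set_score",
    "score_correlation",
    "random_geneset_null",
    "integrated_gradients",
]


@dataclass
class GeneSetScore:
    cell_ids: list[str]
    scores: np.ndarray
    gene_set: list[str]
    basis: str = "predicted_labels"


@dataclass
class AttributionResult:
    gene_ids: list[str]
    attributions: np.ndarray  # cells × genes
    predicted_class: np.ndarray
    completeness_residual: np.ndarray
    key_genes: dict = field(default_factory=dict)  # class label → ranked gene ids
    n_steps: int = 50
    baseline: str = "zeros"


def find_degs(
    X: ExpressionMatrix,
    labels: np.ndarray,
    n_top: int = 100,
    min_abs_lfc: float = 0.25,
) -> dict[str, list[str]]:
    """Differentially expressed genes between sensitive and resistant cells.

    Two-sided Wilcoxon rank-sum per gene, Benjamini–Hochberg correction, genes
    ranked by adjusted p then |log-fold-change| (difference of class means on
    log-normalized data). Returns ``{"sensitive_up": [...], "resistant_up":
    [...]}``, each at most ``n_top`` genes passing ``min_abs_lfc``.
    """
    labels = np.asarray(labels)
    idx1, idx0 = np.flatnonzero(labels == 1), np.flatnonzero(labels == 0)
    if len(idx1) < 3 or len(idx0) < 3:
        raise ValueError("each class needs at least 3 cells for DEG testing")
    A, B = X.values[idx1], X.values[idx0]
    lfc = A.mean(axis=0) - B.mean(axis=0)
    pvals = np.ones(X.n_genes)
    for j in range(X.n_genes):
        if np.ptp(X.values[:, j]) == 0:
            continue  # constant gene: no evidence
        pvals[j] = stats.ranksums(A[:, j], B[:, j]).pvalue
    padj = multipletests(pvals, method="fdr_bh")[1]
    order = np.lexsort((-np.abs(lfc), padj))  # adjusted p first, then effect
    out = {"sensitive_up": [], "resistant_up": []}
    for j in order:
        if lfc[j] >= min_abs_lfc and len(out["sensitive_up"]) < n_top:
            out["sensitive_up"].append(X.gene_ids[j])
        elif lfc[j] <= -min_abs_lfc and len(out["resistant_up"]) < n_top:
            out["resistant_up"].append(X.gene_ids[j])
    return out


def gene_set_score(
    X: ExpressionMatrix, gene_set: list[str], basis: str = "predicted_labels"
) -> GeneSetScore:
    """Per-cell mean of per-gene z-scored expression over the gene set."""
    present = [g for g in gene_set if g in set(X.gene_ids)]
    if not present:
        raise ValueError("gene set has empty intersection with the matrix genes")
    pos = {g: i for i, g in enumerate(X.gene_ids)}
    sub = X.values[:, [pos[g] for g in present]]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance gene(s) in set: z-score set to 0")
    z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return GeneSetScore(list(X.sample_ids), z.mean(axis=1), present, basis=basis)


def score_correlation(pred_scores: GeneSetScore, true_scores: GeneSetScore) -> tuple[float, float]:
    """Pearson correlation (and r²) between two per-cell score vectors."""
    if pred_scores.cell_ids != true_scores.cell_ids:
        raise ValueError("score vectors must cover the same cells in the same order")
    a, b = pred_scores.scores, true_scores.scores
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: zero variance in a score vector")
    r = float(stats.pearsonr(a, b).statistic)
    return r, r * r


def random_geneset_null(
    X: ExpressionMatrix,
    true_labels: np.ndarray,
    pred_labels: np.ndarray,
    deg_list: list[str] | None = None,
    n_trials: int = 1000,
    seed: int = 0,
    direction: str = "sensitive_up",
) -> tuple[float, np.ndarray, float]:
    """Random-gene-set significance test for the predicted-vs-true score link.

    The observed statistic correlates per-cell scores of the predicted DEG
    list (``deg_list``, or derived from ``pred_labels`` when None) with scores
    of the matching true-label DEG list. Each of ``n_trials`` trials replaces
    the predicted list with a uniformly drawn gene set of identical size and
    recomputes the correlation. Returns ``(observed_r, null_rs, p)`` with the
    add-one estimator p = (1 + #{null ≥ observed}) / (1 + n_trials).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be ≥ 1")
    size = None if deg_list is None else len(deg_list)
    if deg_list is None:
        deg_list = find_degs(X, pred_labels)[direction]
    if not deg_list:
        raise ValueError("empty DEG list")
    true_list = find_degs(X, true_labels, n_top=len(deg_list))[direction]
    if not true_list:
        raise ValueError("no true-label DEGs found to correlate against")
    true_vec = gene_set_score(X, true_list, basis="true_labels")
    obs_vec = gene_set_score(X, deg_list, basis="predicted_labels")
    observed_r, _ = score_correlation(obs_vec, true_vec)
    rng = np.random.default_rng(seed)
    size = size if size is not None else len(deg_list)
    null_rs = np.empty(n_trials)
    for t in range(n_trials):
        genes = [X.gene_ids[i] for i in rng.choice(X.n_genes, size=size, replace=False)]
        vec = gene_set_score(X, genes)
        if np.std(vec.scores) == 0:
            null_rs[t] = 0.0
            continue
        null_rs[t], _ = score_correlation(vec, true_vec)
    p = (1 + int(np.sum(null_rs >= observed_r))) / (1 + n_trials)
    return observed_r, null_rs, p


def integrated_gradients(
    sc_encoder: DAEModel,
    predictor: PredictorModel,
    X_cells: np.ndarray,
    gene_ids: list[str] | None = None,
    baseline: np.ndarray | None = None,
    n_steps: int = 50,
    n_key_genes: int = 100,
) -> AttributionResult:
    """Integrated-gradient attributions of F(x) = P(E_t(x)) per cell and gene.

    IG_i = (x_i − b_i) · ∫₀¹ ∂F/∂x_i at b + t(x − b) dt, approximated by a
    composite trapezoid rule over ``n_steps`` panels (nodes k/m, k = 0..m;
    endpoint weights ½). The trapezoid rule converges quadratically between
    the ReLU kinks, which a one-sided Riemann sum does not — that is what
    makes tight completeness residuals reachable at moderate step counts.
    Zero-expression baseline by default. Completeness |Σ_i IG_i − (F(x) −
    F(b))| is recorded per cell. Key genes per predicted class are ranked by
    the mean signed attribution over that class's cells, oriented toward the
    class: for the sensitive class, genes whose expression pushes the score
    up; for the resistant class, genes pushing it down. (A magnitude ranking
    would conflate the two directions — a strongly resistance-associated gene
    has a large-magnitude negative attribution in sensitive cells.)
    """
    X_cells = np.asarray(X_cells, dtype=np.float64)
    n, G = X_cells.shape
    if baseline is None:
        baseline = np.zeros(G)
    baseline = np.asarray(baseline, dtype=np.float64)
    if baseline.shape != (G,):
        raise ValueError(f"baseline must have width {G}")
    gene_ids = gene_ids if gene_ids is not None else list(getattr(sc_encoder.config, "gene_ids", []) or [f"g{i}" for i in range(G)])

    def forward(x: Tensor) -> Tensor:
        return predictor.forward(sc_encoder.encode_tensor(x))

    diff = X_cells - baseline[None, :]
    grad_sum = np.zeros_like(X_cells)
    for k in range(n_steps + 1):
        point = Tensor(baseline[None, :] + (k / n_steps) * diff, requires_grad=True)
        scores = forward(point)
        scores.sum().backward()  # rows are independent, so ∂Σ/∂x = per-cell grads
        grad_sum += (0.5 if k in (0, n_steps) else 1.0) * point.grad
    attributions = diff * grad_sum / n_steps

    f_x = predictor.forward(sc_encoder.encode_tensor(Tensor(X_cells))).numpy()
    f_b = predictor.forward(sc_encoder.encode_tensor(Tensor(baseline[None, :]))).numpy()[0]
    residual = np.abs(attributions.sum(axis=1) - (f_x - f_b))

    predicted = (f_x >= 0.5).astype(np.int64)
    key_genes: dict[int, list[str]] = {}
    for cls in (0, 1):
        members = predicted == cls
        if not members.any():
            key_genes[cls] = []
            continue
        mean_att = attributions[members].mean(axis=0)
        oriented = mean_att if cls == 1 else -mean_att
        order = np.argsort(-oriented)[:n_key_genes]
        key_genes[cls] = [gene_ids[i] for i in order]
    return AttributionResult(
        gene_ids=gene_ids,
        attributions=attributions,
        predicted_class=predicted,
        completeness_residual=residual,
        key_genes=key_genes,
        n_steps=n_steps,
        baseline="zeros" if not baseline.any() else "custom",
    )
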