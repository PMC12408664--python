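"""Quality-control filtering, normalization, class balancing, and splitting.

QC follows the standard droplet-data recipe with strict thresholds: drop cells
detecting fewer than ``min_genes_per_cell`` genes, drop genes detected in fewer
than ``min_cells_per_gene`` cells, drop cells whose mitochondrial share of
total counts exceeds ``max_mito_frac``. The filter order (cells → genes →
mito) is fixed and recorded in the QCReport, because the order changes the
marginal removal counts.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .datamodel import ExpressionMatrix, QCReport, ResponseLabels

__all__ = ["qc_filter", "normalize_log", "balance_classes", "split_train_test"]


def qc_filter(
    X: ExpressionMatrix,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
    max_mito_frac: float = 0.10,
    mito_gene_prefix: str = "MT-",
) -> tuple[ExpressionMatrix, QCReport]:
    """Filter low-quality cells and rarely detected genes from raw counts.

    All thresholds are strict: a cell detecting exactly ``min_genes_per_cell``
    genes is kept, a gene detected in exactly ``min_cells_per_gene`` cells is
    kept, and a cell at exactly ``max_mito_frac`` mitochondrial share is kept.
    Mitochondrial genes are recognized by a case-insensitive id prefix.
    """
    if X.layer != "counts":
        raise ValueError("qc_filter expects the raw-count layer")
    report = QCReport(
        thresholds={
            "min_genes_per_cell": min_genes_per_cell,
            "min_cells_per_gene": min_cells_per_gene,
            "max_mito_frac": max_mito_frac,
            "mito_gene_prefix": mito_gene_prefix,
        }
    )
    vals = X.values

    # 1. cells by detected-gene count
    detected = (vals > 0).sum(axis=1)
    keep_cells = detected >= min_genes_per_cell
    report.cells_removed_low_genes = int((~keep_cells).sum())
    X = X.subset_samples(np.flatnonzero(keep_cells))

    # 2. genes by detecting-cell count
    ncells = (X.values > 0).sum(axis=0)
    keep_genes = ncells >= min_cells_per_gene
    report.genes_removed_low_cells = int((~keep_genes).sum())
    X = X.subset_genes(np.flatnonzero(keep_genes))

    # 3. cells by mitochondrial fraction
    prefix = mito_gene_prefix.lower()
    mito = np.array([g.lower().startswith(prefix) for g in X.gene_ids], dtype=bool)
    totals = X.values.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, X.values[:, mito].sum(axis=1) / totals, 0.0)
    keep_mito = frac <= max_mito_frac
    report.cells_removed_mito = int((~keep_mito).sum())
    X = X.subset_samples(np.flatnonzero(keep_mito))

    if X.n_samples == 0:
        raise ValueError("empty matrix after QC: all cells removed")
    return X, report


def normalize_log(X: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then apply ln(1+x)."""
    if X.layer != "counts":
        raise ValueError("normalize_log expects the raw-count layer")
    totals = X.values.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("cell(s) with zero total counts; run qc_filter first")
    scaled = X.values * (target_sum / totals)[:, None]
    return ExpressionMatrix(
        np.log1p(scaled), list(X.sample_ids), list(X.gene_ids), domain=X.domain, layer="lognorm"
    )


def _smote(
    minority: np.ndarray, n_new: int, k_neighbors: int, rng: np.random.Generator
) -> np.ndarray:
    """Interpolated minority samples: x_i + u·(x_nn − x_i), u ~ U(0,1)."""
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(minority)
    _, idx = nn.kneighbors(minority)  # column 0 is the point itself
    base = rng.integers(0, len(minority), size=n_new)
    pick = rng.integers(1, k_neighbors + 1, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    neighbors = minority[idx[base, pick]]
    return minority[base] + u[:, None] * (neighbors - minority[base])


def balance_classes(
    X: ExpressionMatrix,
    y: ResponseLabels,
    method: str = "oversample",
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ResponseLabels]:
    """Equalize class counts by SMOTE interpolation or duplication.

    Synthetic/duplicated rows get fresh sample ids (``<method><i>_<class>``);
    majority rows pass through untouched. ``method="none"`` is a no-op.
    """
    if method == "none":
        return X, y
    if method not in ("smote", "oversample"):
        raise ValueError(f"unknown balancing method {method!r}")
    classes, counts = np.unique(y.labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balancing requires both classes present")
    if counts[0] == counts[1]:
        return X, y
    minority_class = classes[np.argmin(counts)]
    n_new = int(abs(counts[0] - counts[1]))
    min_idx = np.flatnonzero(y.labels == minority_class)
    minority = X.values[min_idx]
    rng = np.random.default_rng(seed)

    if method == "smote":
        if len(min_idx) <= k_neighbors:
            raise ValueError(
                f"SMOTE needs minority count > k_neighbors ({k_neighbors}); "
                f"got {len(min_idx)} — use a smaller k"
            )
        new_rows = _smote(minority, n_new, k_neighbors, rng)
    else:
        picks = rng.integers(0, len(min_idx), size=n_new)
        new_rows = minority[picks]

    new_ids = [f"{method}{i}_{minority_class}" for i in range(n_new)]
    Xb = ExpressionMatrix(
        np.vstack([X.values, new_rows]),
        list(X.sample_ids) + new_ids,
        list(X.gene_ids),
        domain=X.domain,
        layer=X.layer,
    )
    yb = ResponseLabels(
        list(y.sample_ids) + new_ids,
        np.concatenate([y.labels, np.full(n_new, minority_class)]),
        provenance=y.provenance,
    )
    return Xb, yb


def split_train_test(
    X: ExpressionMatrix,
    y: ResponseLabels,
    test_frac: float = 0.20,
    stratified: bool = True,
    seed: int = 0,
):
    """Disjoint, exhaustive train/test partition (default 80/20, stratified)."""
    if not (0.0 < test_frac < 1.0):
        raise ValueError("test_frac must lie in (0,1)")
    n = X.n_samples
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    n_test = int(round(test_frac * n))
    strat = y.labels if stratified else None
    if stratified and len(np.unique(y.labels)) < 2:
        raise ValueError("stratified split requires both classes present")
    train_idx, test_idx = train_test_split(
        np.arange(n), test_size=n_test, stratify=strat, random_state=seed
    )
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    return (X.subset_samples(train_idx), y.subset(train_idx)), (
        X.subset_samples(test_idx),
        y.subset(test_idx),
    )
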