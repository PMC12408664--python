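"""Core domain types: expression matrices, response labels, QC reports."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionMatrix", "ResponseLabels", "QCReport"]

DOMAINS = ("bulk", "single_cell")


@dataclass
class ExpressionMatrix:
    """A samples × genes expression matrix with identifiers and a domain tag.

    ``layer`` tracks what the values are: ``"counts"`` (raw, integer-valued,
    non-negative) or ``"lognorm"`` (library-size normalized, log1p-transformed).
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    domain: str = "single_cell"
    layer: str = "counts"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}, got {self.domain!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples × genes)")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if self.layer == "counts":
            if np.any(self.values < 0):
                raise ValueError("raw counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_samples(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.values[idx],
            [self.sample_ids[i] for i in idx],
            list(self.gene_ids),
            domain=self.domain,
            layer=self.layer,
        )

    def subset_genes(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.sample_ids),
            [self.gene_ids[i] for i in idx],
            domain=self.domain,
            layer=self.layer,
        )


@dataclass
class ResponseLabels:
    """Per-sample binary drug-response labels (0 = resistant, 1 = sensitive).

    ``scores`` optionally carries the continuous sensitivity probabilities the
    labels were thresholded from; ``provenance`` records whether labels are
    experimental ground truth or model predictions.
    """

    sample_ids: list[str]
    labels: np.ndarray
    provenance: str = "ground_truth"
    scores: np.ndarray | None = None

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.provenance not in ("ground_truth", "predicted"):
            raise ValueError("provenance must be 'ground_truth' or 'predicted'")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary {0,1}")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels and sample_ids length mismatch")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=np.float64)
            if self.scores.shape != self.labels.shape:
                raise ValueError("scores must align with sample_ids")
            if np.any((self.scores < 0) | (self.scores > 1)):
                raise ValueError("scores must lie in [0,1]")

    def subset(self, idx) -> "ResponseLabels":
        idx = np.asarray(idx)
        return ResponseLabels(
            [self.sample_ids[i] for i in idx],
            self.labels[idx],
            provenance=self.provenance,
            scores=None if self.scores is None else self.scores[idx],
        )


@dataclass
class QCReport:
    """Record of what a QC pass removed and under which thresholds."""

    cells_removed_low_genes: int = 0
    genes_removed_low_cells: int = 0
    cells_removed_mito: int = 0
    thresholds: dict = field(default_factory=dict)
    filter_order: tuple = ("cells_by_genes", "genes_by_cells", "mito")
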