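"""Readers and writers for expression matrices: CSV/TSV, MatrixMarket, H5AD.

Conventions:
- CSV/TSV: samples × genes, header row = gene ids, first column = sample ids.
- MTX: scipy MatrixMarket triplet with ``<stem>_rows.txt`` (sample ids) and
  ``<stem>_cols.txt`` (gene ids) sidecars, one id per line.
- H5AD: AnnData with the matrix in ``X``, sample ids in ``obs.index``, gene ids
  in ``var.index``; labels optionally in an obs column.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datamodel import ExpressionMatrix, ResponseLabels

__all__ = ["read_expression", "write_expression", "read_labels_csv", "write_labels_csv"]


def _sidecar_paths(path: str) -> tuple[str, str]:
    stem = path[:-4] if path.endswith(".mtx") else path
    return stem + "_rows.txt", stem + "_cols.txt"


def read_expression(
    path: str,
    format: str | None = None,
    domain: str = "single_cell",
    layer: str = "counts",
    transposed: bool = False,
    label_column: str | None = None,
):
    """Read an expression matrix; returns ExpressionMatrix (and labels for h5ad).

    ``transposed`` declares the on-disk orientation as genes × samples, in
    which case the matrix is transposed to the in-memory samples × genes
    convention. For h5ad, if ``label_column`` names an obs column, a
    ``(ExpressionMatrix, ResponseLabels)`` pair is returned.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".csv": "csv", ".tsv": "csv", ".txt": "csv", ".mtx": "mtx", ".h5ad": "h5ad"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer format from {path!r}; pass format=")
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    if format == "csv":
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, ValueError) as e:
            raise ValueError(f"malformed delimited file {path!r}: {e}") from e
        values = df.to_numpy(dtype=np.float64)
        rows, cols = list(df.index.astype(str)), list(df.columns.astype(str))
    elif format == "mtx":
        rows_path, cols_path = _sidecar_paths(path)
        for sidecar in (rows_path, cols_path):
            if not os.path.exists(sidecar):
                raise FileNotFoundError(f"MTX sidecar missing: {sidecar}")
        try:
            mat = spio.mmread(path)
        except ValueError as e:
            raise ValueError(f"malformed MatrixMarket file {path!r}: {e}") from e
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=np.float64)
        rows = [ln.strip() for ln in open(rows_path) if ln.strip()]
        cols = [ln.strip() for ln in open(cols_path) if ln.strip()]
    elif format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        values = np.asarray(X.todense() if sparse.issparse(X) else X, dtype=np.float64)
        rows = list(adata.obs_names.astype(str))
        cols = list(adata.var_names.astype(str))
        if label_column is not None:
            if label_column not in adata.obs.columns:
                raise KeyError(f"obs column {label_column!r} not found in {path!r}")
            labels = ResponseLabels(rows, adata.obs[label_column].to_numpy())
            xm = ExpressionMatrix(values, rows, cols, domain=domain, layer=layer)
            return xm, labels
    else:
        raise ValueError(f"unknown format {format!r}")

    if transposed:
        values = values.T
        rows, cols = cols, rows
    return ExpressionMatrix(values, rows, cols, domain=domain, layer=layer)


def write_expression(X: ExpressionMatrix, path: str, format: str | None = None) -> None:
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".csv": "csv", ".tsv": "csv", ".mtx": "mtx", ".h5ad": "h5ad"}.get(ext, "csv")
    if format == "csv":
        sep = "\t" if path.endswith(".tsv") else ","
        pd.DataFrame(X.values, index=X.sample_ids, columns=X.gene_ids).to_csv(path, sep=sep)
    elif format == "mtx":
        rows_path, cols_path = _sidecar_paths(path)
        spio.mmwrite(path, sparse.coo_matrix(X.values))
        with open(rows_path, "w") as fh:
            fh.write("\n".join(X.sample_ids) + "\n")
        with open(cols_path, "w") as fh:
            fh.write("\n".join(X.gene_ids) + "\n")
    elif format == "h5ad":
        import anndata as ad
        import pandas as pd_

        adata = ad.AnnData(
            X=X.values,
            obs=pd_.DataFrame(index=pd_.Index(X.sample_ids, name="cell_id")),
            var=pd_.DataFrame(index=pd_.Index(X.gene_ids, name="gene_id")),
        )
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels_csv(path: str, provenance: str = "ground_truth") -> ResponseLabels:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "label" not in df.columns:
        # fall back to first-two-column convention
        df = pd.read_csv(path, header=0)
        df.columns = ["sample_id", "label", *df.columns[2:]]
    scores = df["score"].to_numpy() if "score" in df.columns else None
    return ResponseLabels(
        list(df["sample_id"].astype(str)), df["label"].to_numpy(), provenance=provenance, scores=scores
    )


def write_labels_csv(y: ResponseLabels, path: str) -> None:
    cols = {"sample_id": y.sample_ids, "label": y.labels}
    if y.scores is not None:
        cols["score"] = y.scores
    pd.DataFrame(cols).to_csv(path, index=False)
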