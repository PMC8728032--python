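"""Readers/writers for the on-disk formats and the expression-preprocessing
utilities.

Disk orientation is genes x samples (dense TSV/CSV with gene ids in the first
column and sample ids in the header; MatrixMarket triplet + row/column id
sidecars for sparse single-cell matrices); tests consume samples x genes,
obtained through :class:`~gsabench.datasets.ExpressionDataset` accessors.
Gene-id matching is exact string match throughout.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datasets import ExpressionDataset, GeneSetCollection
from .errors import DataError, ParameterError

logger = logging.getLogger("gsabench")

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_labels",
    "write_labels",
    "quantile_normalize",
    "top_variable_genes",
]


def _check_ids(ids: list[str], what: str, path) -> None:
    seen: dict[str, int] = {}
    for lineno, ident in enumerate(ids):
        if ident in seen:
            raise DataError(
                f"{path}: duplicate {what} id {ident!r} "
                f"(entries {seen[ident] + 1} and {lineno + 1})"
            )
        seen[ident] = lineno


def read_expression(path: str | Path, format: str | None = None) -> ExpressionDataset:
    """Read a genes x samples expression matrix.

    Dense ``tsv``/``csv``: first column gene ids, header row sample ids.
    ``mtx_dir``: a directory containing ``matrix.mtx`` (MatrixMarket triplet,
    genes as rows), ``genes.tsv`` and ``samples.tsv`` (one id per line).
    Sparse input stays sparse; it is densified only on gene-subset extraction.
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "mtx_dir"
        elif path.suffix == ".csv":
            format = "csv"
        else:
            format = "tsv"

    if format == "mtx_dir":
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        samples_f = path / "samples.tsv"
        for f in (mtx, genes_f, samples_f):
            if not f.exists():
                raise DataError(f"{path}: missing {f.name}")
        matrix = scipy.io.mmread(mtx).tocsr()
        gene_ids = [ln.split("\t")[0] for ln in genes_f.read_text().splitlines() if ln]
        sample_ids = [ln.split("\t")[0] for ln in samples_f.read_text().splitlines() if ln]
        _check_ids(gene_ids, "gene", genes_f)
        _check_ids(sample_ids, "sample", samples_f)
        if matrix.shape != (len(gene_ids), len(sample_ids)):
            raise DataError(
                f"{mtx}: matrix is {matrix.shape}, sidecars list "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        return ExpressionDataset(matrix, gene_ids, sample_ids)

    if format not in ("tsv", "csv"):
        raise ParameterError(f"unknown expression format {format!r}")
    sep = "\t" if format == "tsv" else ","
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise DataError(f"{path}: {exc}") from exc
    gene_ids = [str(g) for g in frame.index]
    sample_ids = [str(s) for s in frame.columns]
    _check_ids(gene_ids, "gene", path)
    _check_ids(sample_ids, "sample", path)
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for col in frame.columns:
            bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
            if bad.any():
                row = int(np.where(bad)[0][0])
                raise DataError(
                    f"{path}: non-numeric value {frame[col].iloc[row]!r} at "
                    f"gene {gene_ids[row]!r}, column {col!r} (line {row + 2})"
                )
        raise DataError(f"{path}: matrix contains non-numeric cells")
    return ExpressionDataset(values.astype(float), gene_ids, sample_ids)


def write_expression(expr: ExpressionDataset, path: str | Path, format: str = "tsv") -> None:
    """Write a dense genes x samples TSV/CSV (gene ids first column)."""
    if format not in ("tsv", "csv"):
        raise ParameterError(f"unknown expression format {format!r}")
    frame = expr.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t" if format == "tsv" else ",")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: tab-separated name, description, gene ids.

    File order is preserved; trailing empty fields are tolerated; duplicate
    genes within a line are removed with a log notice. An empty file yields
    an empty collection.
    """
    path = Path(path)
    sets = GeneSetCollection()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        while fields and fields[-1] == "":
            fields.pop()
        if len(fields) < 3:
            raise DataError(
                f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                "expected name, description and at least one gene"
            )
        sets.add(fields[0], fields[1], fields[2:])
    return sets


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, sets.description(name), *sets.genes(name)])
        for name in sets
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample_id, label in {0,1}) into a Series."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if frame.shape[1] != 2:
        raise DataError(f"{path}: expected 2 columns, found {frame.shape[1]}")
    ids = frame.iloc[:, 0].astype(str)
    _check_ids(list(ids), "sample", path)
    labels = pd.to_numeric(frame.iloc[:, 1], errors="coerce")
    if labels.isna().any() or not set(labels.unique()) <= {0, 1}:
        raise DataError(f"{path}: labels must be 0/1")
    return pd.Series(labels.astype(int).to_numpy(), index=list(ids), name="label")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    frame = pd.DataFrame({"sample_id": labels.index, "label": labels.to_numpy()})
    frame.to_csv(path, sep="\t", index=False)


def quantile_normalize(expr: ExpressionDataset) -> ExpressionDataset:
    """Quantile-normalise samples: each column's sorted values are replaced
    by the across-column mean of sorted values, so all columns end with the
    identical value multiset. Ties within a column receive the mean of the
    reference values their positions span."""
    if expr.n_samples < 2:
        raise DataError("quantile normalisation needs >= 2 samples")
    x = expr.to_frame().to_numpy()
    if not np.isfinite(x).all():
        raise DataError("matrix contains non-finite entries")
    reference = np.sort(x, axis=0).mean(axis=1)
    normalized = np.empty_like(x, dtype=float)
    for j in range(x.shape[1]):
        idx = np.argsort(x[:, j], kind="stable")
        sorted_col = x[idx, j]
        _, inverse, counts = np.unique(
            sorted_col, return_inverse=True, return_counts=True
        )
        group_means = np.bincount(inverse, weights=reference) / counts
        normalized[idx, j] = group_means[inverse]
    return ExpressionDataset(
        normalized,
        list(expr.gene_ids),
        list(expr.sample_ids),
        labels=None if expr.labels is None else expr.labels.copy(),
        gene_sets=expr.gene_sets,
    )


def top_variable_genes(expr: ExpressionDataset, k: int) -> ExpressionDataset:
    """The k genes with the largest sample variance (descending; input order
    breaks ties), as used to pre-filter sparse single-cell matrices before
    MVN testing."""
    if k < 1 or k > expr.n_genes:
        raise ParameterError(f"k={k} outside 1..{expr.n_genes}")
    dense = expr.to_frame().to_numpy()
    variances = dense.var(axis=1, ddof=1)
    order = np.argsort(-variances, kind="stable")[:k]
    gene_ids = [expr.gene_ids[i] for i in order]
    return ExpressionDataset(
        dense[order],
        gene_ids,
        list(expr.sample_ids),
        labels=None if expr.labels is None else expr.labels.copy(),
        gene_sets=expr.gene_sets,
    )
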