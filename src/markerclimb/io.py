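"""Reading counts and cluster metadata, gene filtering, log-normalization.

The canonical in-memory orientation is genes x cells. On-disk matrices may be
stored either way (cells x genes is common in MTX exports); ``transpose=True``
tells the reader that rows on disk are cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ClusterLabels",
    "NormalizedMatrix",
    "read_counts",
    "read_cluster_labels",
    "filter_genes",
    "log_normalize",
    "write_marker_table",
]

MARKER_TABLE_COLUMNS = ["cluster", "gene", "selected", "marker_score", "log2fc", "p_adj", "rank"]


def _check_unique(ids: np.ndarray, axis: str) -> None:
    vals, counts = np.unique(ids, return_counts=True)
    dups = vals[counts > 1]
    if dups.size:
        raise ValueError(f"duplicate {axis} identifiers: {', '.join(map(str, dups[:10]))}")


@dataclass
class CountMatrix:
    """Raw genes x cells count matrix with identifier sidecars."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be two-dimensional")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.values, 1), 0)):
                raise ValueError("count matrix contains non-integer values")
            self.values = self.values.astype(np.int64)
        if (self.values < 0).any():
            raise ValueError("count matrix contains negative values")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusterLabels:
    """Per-cell cluster assignment (cell_id -> categorical label)."""

    assignment: pd.Series
    cluster_names: list = field(init=False)

    def __post_init__(self) -> None:
        self.assignment = pd.Series(self.assignment).astype(str)
        if self.assignment.index.has_duplicates:
            raise ValueError("duplicate cell identifiers in cluster metadata")
        # first-appearance order, stable across runs
        self.cluster_names = list(dict.fromkeys(self.assignment))
        if len(self.cluster_names) < 2:
            raise ValueError("at least 2 distinct clusters are required for one-vs-rest testing")

    def for_cells(self, cell_ids: np.ndarray) -> np.ndarray:
        """Labels aligned to ``cell_ids``; every cell must be labelled."""
        missing = [c for c in cell_ids if c not in self.assignment.index]
        if missing:
            raise ValueError(f"cells without cluster label: {', '.join(map(str, missing[:10]))}")
        return self.assignment.loc[list(cell_ids)].to_numpy()


@dataclass
class NormalizedMatrix:
    """log1p of library-size-scaled counts (natural log), genes x cells."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    target_sum: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if (self.values < 0).any():
            raise ValueError("normalized matrix contains negative values")

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as e:
            raise KeyError(f"gene {e.args[0]!r} not present in normalized matrix") from None


def read_counts(
    path,
    format: str = "mtx",
    gene_sidecar=None,
    cell_sidecar=None,
    transpose: bool = False,
) -> CountMatrix:
    """Read a count matrix from Matrix Market triplet or dense delimited form.

    Parameters
    ----------
    format
        ``"mtx"`` (requires gene/cell sidecar files, one identifier per line)
        or ``"dense"`` (gene ids in the first column, cell ids in the header).
    transpose
        If True, rows on disk are cells and columns are genes.
    """
    path = Path(path)
    if format == "mtx":
        if gene_sidecar is None or cell_sidecar is None:
            raise ValueError("matrix-market input requires gene and cell sidecar files")
        mat = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        genes = np.array(Path(gene_sidecar).read_text().split(), dtype=object)
        cells = np.array(Path(cell_sidecar).read_text().split(), dtype=object)
    elif format == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        mat = df.to_numpy()
        genes = df.index.to_numpy(dtype=object)
        cells = df.columns.to_numpy(dtype=object)
        if transpose:
            genes, cells = cells, genes
    else:
        raise ValueError(f"unknown format {format!r}; expected 'mtx' or 'dense'")
    if transpose:
        mat = mat.T
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    return CountMatrix(values=mat, gene_ids=genes, cell_ids=cells)


def read_cluster_labels(path, cluster_col: str, cell_col: str = "cell_id") -> ClusterLabels:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (cell_col, cluster_col):
        if col not in df.columns:
            raise ValueError(f"metadata file {path} has no column {col!r}")
    return ClusterLabels(pd.Series(df[cluster_col].to_numpy(), index=df[cell_col].to_numpy()))


def filter_genes(m: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Keep genes with nonzero counts in at least ``min_cells`` cells."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    keep = (m.values > 0).sum(axis=1) >= min_cells
    if not keep.any():
        raise ValueError(f"no genes expressed in >= {min_cells} cells; empty feature space")
    return CountMatrix(m.values[keep], m.gene_ids[keep], m.cell_ids)


def log_normalize(m: CountMatrix, target_sum: float = 1e4) -> NormalizedMatrix:
    """Scale each cell to ``target_sum`` total counts, then log1p (natural log).

    Cells with zero total counts are dropped with a warning.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = m.values.sum(axis=0)
    nonzero = totals > 0
    if not nonzero.all():
        logger.warning("dropping %d cells with zero total counts", int((~nonzero).sum()))
    vals = m.values[:, nonzero].astype(float)
    scaled = vals * (target_sum / totals[nonzero])
    return NormalizedMatrix(
        values=np.log1p(scaled),
        gene_ids=m.gene_ids,
        cell_ids=m.cell_ids[nonzero],
        target_sum=float(target_sum),
    )


def write_marker_table(results: pd.DataFrame, path) -> None:
    """Write selected markers as TSV, ordered by cluster then descending score.

    ``results`` carries one row per (cluster, gene) with a ``selected`` flag;
    only selected rows are written. Clusters present in the table but with an
    empty selection contribute no data rows and are logged.
    """
    required = {"cluster", "gene", "selected", "marker_score", "log2fc", "p_adj"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    out = results[results["selected"].astype(bool)].copy()
    for cluster in pd.unique(results["cluster"]):
        if not (out["cluster"] == cluster).any():
            logger.warning("cluster %s has an empty marker selection", cluster)
    out = out.sort_values(["cluster", "marker_score"], ascending=[True, False], kind="stable")
    out["rank"] = out.groupby("cluster", sort=False).cumcount() + 1
    out = out[MARKER_TABLE_COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
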