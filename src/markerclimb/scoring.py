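"""Coefficient structures for the selection objective.

The per-gene marker score compares a gene's differential-expression strength
in the target cluster against its strength everywhere else: genes that are
differential only in the target score high, genes that are differential in
many clusters score near or below zero. The DE factor of a gene in a cluster
is the absolute one-vs-rest log2 fold change, and

    score(g) = log2( (DEfactor_target(g) + eps) / (mean_{c' != target} DEfactor_c'(g) + eps) )

Pairwise cosine similarities over the candidate pool supply the redundancy
penalty's coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import cosine_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "CandidatePool",
    "GeneSimilarityMatrix",
    "marker_scores",
    "marker_gene_score",
    "candidate_pool",
    "cosine_similarity_matrix",
    "cluster_mean_profiles",
]

PSEUDOCOUNT = 1e-9


@dataclass
class CandidatePool:
    """DE-filtered gene subset the optimizer works over."""

    target_cluster: str
    genes: np.ndarray
    selection_basis: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("candidate pool contains duplicate genes")
        if len(self.genes) < 2:
            raise ValueError("candidate pool must contain at least 2 genes")


@dataclass
class GeneSimilarityMatrix:
    """Symmetric pairwise cosine similarities over a candidate pool."""

    genes: np.ndarray
    sim: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.sim = np.asarray(self.sim, dtype=float)
        n = len(self.genes)
        if self.sim.shape != (n, n):
            raise ValueError("similarity matrix shape does not match pool size")


def _de_factor_table(de: pd.DataFrame) -> pd.DataFrame:
    """clusters x genes table of |log2FC| one-vs-rest DE factors."""
    return de.pivot(index="cluster", columns="gene", values="lfc").abs()


def marker_scores(de: pd.DataFrame, cluster) -> pd.Series:
    """Per-gene marker score for ``cluster`` (the c1 coefficients)."""
    factors = _de_factor_table(de)
    cluster = str(cluster)
    if cluster not in factors.index:
        raise ValueError(f"cluster {cluster!r} not present in DE results")
    if len(factors.index) < 2:
        raise ValueError("marker scores require at least 2 clusters")
    target = factors.loc[cluster]
    others = factors.drop(index=cluster).mean(axis=0)
    return np.log2((target + PSEUDOCOUNT) / (others + PSEUDOCOUNT)).rename("marker_score")


def marker_gene_score(de: pd.DataFrame, cluster, gene) -> float:
    return float(marker_scores(de, cluster)[gene])


def candidate_pool(de: pd.DataFrame, cluster, n_pool: int = 50, alpha: float = 0.05) -> CandidatePool:
    """Significant genes for the target cluster ranked by descending lfc.

    Genes with ``p_adj <= alpha`` in the target cluster's one-vs-rest test are
    kept, ordered by descending log2 fold change (gene-id order breaks ties),
    and truncated to ``n_pool``. If fewer than 2 genes survive the filter the
    pool falls back to the top ``n_pool`` by lfc regardless of significance.
    """
    if n_pool < 2:
        raise ValueError("n_pool must be >= 2")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    cluster = str(cluster)
    sub = de[de["cluster"] == cluster]
    if sub.empty:
        raise ValueError(f"cluster {cluster!r} not present in DE results")
    sub = sub.sort_values(["lfc", "gene"], ascending=[False, True], kind="stable")
    significant = sub[sub["p_adj"] <= alpha]
    fallback = len(significant) < 2
    if fallback:
        logger.warning(
            "cluster %s: %d genes pass p_adj <= %g; falling back to top-%d by lfc",
            cluster, len(significant), alpha, n_pool,
        )
        significant = sub
    genes = significant["gene"].to_numpy(dtype=object)[:n_pool]
    return CandidatePool(
        target_cluster=cluster,
        genes=genes,
        selection_basis={"alpha": alpha, "n_pool": n_pool, "fallback": fallback},
    )


def cosine_similarity_matrix(norm, pool: CandidatePool) -> GeneSimilarityMatrix:
    """Pairwise cosine similarity of log-normalized gene profiles over all cells.

    Genes with an all-zero profile get similarity 0 to every other gene and 1
    to themselves by convention.
    """
    if len(pool.genes) == 0:
        raise ValueError("candidate pool is empty")
    idx = norm.gene_index(pool.genes)
    profiles = norm.values[idx]
    norms = np.linalg.norm(profiles, axis=1)
    sim = cosine_similarity(profiles)
    zero = norms == 0
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.fill_diagonal(sim, 1.0)
    # profiles are non-negative, so true cosines lie in [0, 1]
    sim = np.clip(sim, 0.0, 1.0)
    return GeneSimilarityMatrix(genes=pool.genes, sim=sim)


def cluster_mean_profiles(norm, labels, genes) -> pd.DataFrame:
    """clusters x genes table of mean log-normalized expression."""
    idx = norm.gene_index(genes)
    lab = labels.for_cells(norm.cell_ids)
    rows = {}
    for cluster in labels.cluster_names:
        mask = lab == cluster
        if not mask.any():
            raise ValueError(f"cluster {cluster!r} has no cells in the matrix")
        rows[cluster] = norm.values[idx][:, mask].mean(axis=1)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(genes))
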