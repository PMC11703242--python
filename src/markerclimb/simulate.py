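"""Clustered negative-binomial count simulator with planted markers.

Emulates a clustered scRNA-seq count matrix: every gene has a baseline
negative-binomial mean, each cluster gets a disjoint block of planted marker
genes whose mean is shifted up by ``2**log2_effect`` in that cluster, and
per-cell library sizes vary log-normally. ``overlap`` leaks a fraction of
each cluster's marker effect into one designated neighbor cluster
(cluster c's markers leak into cluster (c+1) mod K), moving the data from a
well-separated to an overlapping-cluster regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .io import ClusterLabels, CountMatrix

__all__ = ["SimulationConfig", "GroundTruth", "simulate_counts", "recovery_metrics", "write_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the clustered count generator.

    dispersion is the negative-binomial size parameter theta
    (var = mu + mu^2/theta); libsize_sigma the sigma of the log-normal
    per-cell library factor.
    """

    n_genes: int = 2000
    n_cells: int = 1500
    n_clusters: int = 5
    markers_per_cluster: int = 10
    log2_effect: float = 4.0
    overlap: float = 0.0
    baseline_mean: float = 1.0
    dispersion: float = 2.0
    libsize_sigma: float = 0.3
    seed: int = 0
    cluster_sizes: tuple | None = None  # override for imbalance experiments

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells", "n_clusters", "markers_per_cluster"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_clusters * self.markers_per_cluster > self.n_genes:
            raise ValueError("more planted markers than genes")
        if not 0 <= self.overlap <= 1:
            raise ValueError("overlap must lie in [0, 1]")
        if min(self.baseline_mean, self.dispersion) <= 0 or self.log2_effect < 0:
            raise ValueError("baseline_mean and dispersion must be positive, log2_effect non-negative")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be non-negative")
        sizes = self.sizes()
        if len(sizes) != self.n_clusters or sum(sizes) != self.n_cells:
            raise ValueError("cluster_sizes must have n_clusters entries summing to n_cells")
        if min(sizes) < 10:
            raise ValueError("every cluster needs at least 10 cells")

    def sizes(self) -> list[int]:
        if self.cluster_sizes is not None:
            return [int(s) for s in self.cluster_sizes]
        base, extra = divmod(self.n_cells, self.n_clusters)
        return [base + (1 if i < extra else 0) for i in range(self.n_clusters)]


@dataclass
class GroundTruth:
    """Planted marker identities and their per-cluster log2 effects."""

    markers: dict = field(default_factory=dict)  # cluster -> list of gene ids
    effects: pd.DataFrame = None  # tidy: cluster, gene, log2_effect

    def planted(self, cluster) -> set:
        cluster = str(cluster)
        if cluster not in self.markers:
            raise ValueError(f"unknown cluster {cluster!r}")
        return set(self.markers[cluster])


def simulate_counts(cfg: SimulationConfig):
    """Draw a (CountMatrix, ClusterLabels, GroundTruth) triple from ``cfg``.

    Gene g in a cell of cluster c has NB mean
    mu_gc = baseline_mean * libfactor(cell) * 2**E_gc, where E_gc is
    log2_effect for c's own markers, overlap*log2_effect for the markers of
    c's designated neighbor, and 0 otherwise. Cells are assigned to clusters
    in contiguous blocks.
    """
    rng = np.random.default_rng(cfg.seed)
    g, n, k = cfg.n_genes, cfg.n_cells, cfg.n_clusters
    gene_ids = np.array([f"g{i:05d}" for i in range(g)], dtype=object)
    cell_ids = np.array([f"c{i:05d}" for i in range(n)], dtype=object)
    cluster_names = [f"cluster{i}" for i in range(k)]

    sizes = cfg.sizes()
    cell_cluster = np.repeat(np.arange(k), sizes)

    marker_idx = rng.permutation(g)[: k * cfg.markers_per_cluster].reshape(k, cfg.markers_per_cluster)

    # per-gene log2 effect in each cluster
    effect = np.zeros((g, k))
    for c in range(k):
        effect[marker_idx[c], c] += cfg.log2_effect
        effect[marker_idx[c], (c + 1) % k] += cfg.overlap * cfg.log2_effect

    libfactor = np.exp(rng.normal(0.0, cfg.libsize_sigma, size=n)) if cfg.libsize_sigma > 0 else np.ones(n)
    mu = cfg.baseline_mean * (2.0 ** effect[:, cell_cluster]) * libfactor[None, :]
    theta = cfg.dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))

    labels = ClusterLabels(pd.Series([cluster_names[c] for c in cell_cluster], index=cell_ids))
    effects = pd.DataFrame(
        [
            (cluster_names[c], gene_ids[gi], cfg.log2_effect)
            for c in range(k)
            for gi in sorted(marker_idx[c])
        ],
        columns=["cluster", "gene", "log2_effect"],
    )
    truth = GroundTruth(
        markers={cluster_names[c]: [gene_ids[gi] for gi in sorted(marker_idx[c])] for c in range(k)},
        effects=effects,
    )
    return CountMatrix(counts, gene_ids, cell_ids), labels, truth


def recovery_metrics(selected, truth: GroundTruth, cluster):
    """(precision, recall) of a selected gene set against the planted markers."""
    selected = set(selected)
    if not selected:
        raise ValueError("selected gene set is empty")
    planted = truth.planted(cluster)
    hit = len(selected & planted)
    return hit / len(selected), hit / len(planted)


def write_dataset(outdir, counts: CountMatrix, labels: ClusterLabels, truth: GroundTruth | None = None) -> None:
    """Emit the dataset in both supported input encodings plus metadata.

    Writes ``counts.mtx`` + ``genes.txt`` + ``cells.txt``, a dense
    ``counts.tsv``, ``meta.tsv`` (cell_id, cluster) and, when ground truth is
    given, ``truth.tsv`` (cluster, gene, log2_effect).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "counts.mtx"), scipy.sparse.coo_matrix(counts.values), field="integer")
    (outdir / "genes.txt").write_text("\n".join(map(str, counts.gene_ids)) + "\n")
    (outdir / "cells.txt").write_text("\n".join(map(str, counts.cell_ids)) + "\n")
    pd.DataFrame(counts.values, index=counts.gene_ids, columns=counts.cell_ids).to_csv(
        outdir / "counts.tsv", sep="\t"
    )
    pd.DataFrame(
        {"cell_id": counts.cell_ids, "cluster": labels.for_cells(counts.cell_ids)}
    ).to_csv(outdir / "meta.tsv", sep="\t", index=False)
    if truth is not None:
        truth.effects.to_csv(outdir / "truth.tsv", sep="\t", index=False)
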