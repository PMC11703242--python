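"""End-to-end marker selection: preprocess -> DE -> scoring -> hill climb."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import de as de_mod
from .io import ClusterLabels, CountMatrix, filter_genes, log_normalize
from .optimize import ObjectiveConfig, OptimizerParams, hill_climb
from .scoring import candidate_pool, cosine_similarity_matrix, marker_scores

logger = logging.getLogger(__name__)

__all__ = ["MarkerSelectionResult", "select_markers"]


@dataclass
class MarkerSelectionResult:
    """Outputs of a full selection run.

    ``table`` holds one row per (target cluster, pool gene) with the
    ``selected`` flag; ``de`` is the full one-vs-rest DE table; ``objectives``
    and ``traces`` are keyed by target cluster.
    """

    table: pd.DataFrame
    de: pd.DataFrame
    objectives: dict = field(default_factory=dict)
    traces: dict = field(default_factory=dict)

    def selected(self, cluster) -> list:
        sub = self.table[(self.table["cluster"] == str(cluster)) & self.table["selected"]]
        return sub["gene"].tolist()


def select_markers(
    counts: CountMatrix,
    labels: ClusterLabels,
    clusters="all",
    de_method: str = "wilcoxon",
    min_cells: int = 3,
    target_sum: float = 1e4,
    n_pool: int = 50,
    alpha: float = 0.05,
    objective: ObjectiveConfig | None = None,
    optimizer: OptimizerParams | None = None,
) -> MarkerSelectionResult:
    """Run the whole pipeline for one or more target clusters.

    One-vs-rest DE is computed once for every cluster up front (the marker
    score needs all clusters' DE factors) and reused across targets.
    """
    if objective is None:
        objective = ObjectiveConfig()
    if optimizer is None:
        optimizer = OptimizerParams()
    targets = labels.cluster_names if clusters == "all" else [str(c) for c in clusters]
    unknown = [c for c in targets if c not in labels.cluster_names]
    if unknown:
        raise ValueError(f"unknown target clusters: {unknown}")

    filtered = filter_genes(counts, min_cells=min_cells)
    norm = log_normalize(filtered, target_sum=target_sum)
    de_table = de_mod.de_one_vs_rest(norm, labels, method=de_method)

    rows, objectives, traces = [], {}, {}
    for cluster in targets:
        pool = candidate_pool(de_table, cluster, n_pool=n_pool, alpha=alpha)
        scores = marker_scores(de_table, cluster)[pool.genes].to_numpy()
        sim = cosine_similarity_matrix(norm, pool)
        result = hill_climb(scores, sim.sim, objective, optimizer)
        objectives[cluster] = result.objective
        traces[cluster] = result.trace
        de_sub = de_table[de_table["cluster"] == cluster].set_index("gene")
        for g, s, sel in zip(pool.genes, scores, result.x):
            rows.append(
                {
                    "cluster": cluster,
                    "gene": g,
                    "selected": bool(sel),
                    "marker_score": float(s),
                    "log2fc": float(de_sub.loc[g, "lfc"]),
                    "p_adj": float(de_sub.loc[g, "p_adj"]),
                }
            )
        logger.info(
            "cluster %s: pool %d, selected %d, objective %.4f",
            cluster, len(pool.genes), int(result.x.sum()), result.objective,
        )
    table = pd.DataFrame(rows)
    table["rank"] = (
        table.groupby("cluster", sort=False)["marker_score"]
        .rank(ascending=False, method="first")
        .astype(int)
    )
    return MarkerSelectionResult(table=table, de=de_table, objectives=objectives, traces=traces)
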