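"""Benchmark metrics for selected marker sets and cross-dataset ranking.

Two complementary scores: the log-ratio difference (how much higher a marker
is expressed in its cluster than everywhere else — higher is better) and the
median cosine similarity between the target cluster's selected-gene mean
expression vector and each other cluster's (lower means more cluster-specific
markers). Methods are ranked per dataset on the medians and summarized by
mean rank.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scoring import cluster_mean_profiles

__all__ = ["log_ratio_difference", "median_cosine_metric", "rank_methods"]

PSEUDOCOUNT = 1e-9


def log_ratio_difference(norm, labels, cluster, selected_genes):
    """Per-gene log2 in/out expression ratio and its median over the selection.

    Returns
    -------
    (per_gene, median) : pd.Series indexed by gene, and the median across it.
    """
    selected_genes = list(selected_genes)
    if not selected_genes:
        raise ValueError("selected gene set is empty")
    idx = norm.gene_index(selected_genes)
    lab = labels.for_cells(norm.cell_ids)
    if str(cluster) not in set(lab):
        raise ValueError(f"cluster {cluster!r} not present among labelled cells")
    mask = lab == str(cluster)
    expr = np.expm1(norm.values[idx])
    mean_in = expr[:, mask].mean(axis=1)
    mean_out = expr[:, ~mask].mean(axis=1)
    ratios = np.log2((mean_in + PSEUDOCOUNT) / (mean_out + PSEUDOCOUNT))
    per_gene = pd.Series(ratios, index=selected_genes, name="log_ratio")
    return per_gene, float(per_gene.median())


def median_cosine_metric(norm, labels, cluster, selected_genes) -> float:
    """Median cosine between the target's and each other cluster's mean vector.

    The mean vector of a cluster is its per-gene mean log-normalized
    expression over the selected genes. Zero vectors get cosine 0 by
    convention, so markers expressed only in the target cluster score 0.
    """
    selected_genes = list(selected_genes)
    if not selected_genes:
        raise ValueError("selected gene set is empty")
    profiles = cluster_mean_profiles(norm, labels, selected_genes)
    cluster = str(cluster)
    if cluster not in profiles.index:
        raise ValueError(f"cluster {cluster!r} not present among labelled cells")
    others = [c for c in profiles.index if c != cluster]
    if not others:
        raise ValueError("metric requires at least 2 clusters")
    target = profiles.loc[cluster].to_numpy()
    t_norm = np.linalg.norm(target)
    cosines = []
    for other in others:
        vec = profiles.loc[other].to_numpy()
        denom = t_norm * np.linalg.norm(vec)
        cosines.append(float(target @ vec / denom) if denom > 0 else 0.0)
    return float(np.median(cosines))


def rank_methods(metric_medians: pd.DataFrame, higher_is_better: bool) -> pd.DataFrame:
    """Rank methods per dataset and summarize (rank 1 is best).

    Parameters
    ----------
    metric_medians
        methods x datasets table of per-dataset median metric values.

    Returns
    -------
    Frame indexed by method with ``mean_rank`` (ties share the mean rank) and
    ``sd_of_medians`` (standard deviation of the medians across datasets).
    """
    if metric_medians.shape[0] < 2:
        raise ValueError("ranking requires at least 2 methods")
    if metric_medians.shape[1] < 1:
        raise ValueError("ranking requires at least 1 dataset")
    if metric_medians.isna().any().any():
        mask = metric_medians.isna()
        method = mask.any(axis=1).idxmax()
        dataset = mask.loc[method].idxmax()
        raise ValueError(f"missing metric value for method {method!r} on dataset {dataset!r}")
    ranks = metric_medians.rank(axis=0, ascending=not higher_is_better, method="average")
    return pd.DataFrame(
        {
            "mean_rank": ranks.mean(axis=1),
            "sd_of_medians": metric_medians.std(axis=1, ddof=1) if metric_medians.shape[1] > 1 else 0.0,
        }
    )
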