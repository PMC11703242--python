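import numpy as np
import pandas as pd
import pytest

from markerclimb import ClusterLabels, NormalizedMatrix


def make_norm(values, gene_ids=None, cell_ids=None, target_sum=1e4):
    """NormalizedMatrix straight from given (already log-scale) values."""
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(g)]
    if cell_ids is None:
        cell_ids = [f"c{i}" for i in range(c)]
    return NormalizedMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids, target_sum=target_sum)


def make_labels(groups, cell_ids=None):
    """ClusterLabels from a per-cell label sequence."""
    groups = list(groups)
    if cell_ids is None:
        cell_ids = [f"c{i}" for i in range(len(groups))]
    return ClusterLabels(pd.Series(groups, index=cell_ids))


def two_group_norm(a, b):
    """One-gene matrix whose cells split into groups 'A' (values a) and 'B'."""
    vals = np.concatenate([a, b])[None, :]
    labels = make_labels(["A"] * len(a) + ["B"] * len(b))
    return make_norm(vals), labels


@pytest.fixture(scope="session")
def separated_dataset():
    """Well-separated simulated dataset shared across slower tests."""
    from markerclimb import SimulationConfig, simulate_counts

    cfg = SimulationConfig(
        n_genes=400, n_cells=600, n_clusters=3, markers_per_cluster=8,
        log2_effect=4.0, overlap=0.0, seed=11,
    )
    return simulate_counts(cfg)
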