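"""One-vs-rest differential expression on log-normalized data.

Fold changes are computed on the library-size-normalized scale (expm1 of the
log-normalized values) with a small pseudocount so they stay finite. The
Wilcoxon rank-sum test uses an exact null distribution for small tie-free
groups and a tie-corrected normal approximation with continuity correction
otherwise; the t-test is Welch's with a variance floor for constant groups.
Both are implemented here; p-values are BH-adjusted per cluster across genes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "log2_fold_change",
    "wilcoxon_one_vs_rest",
    "ttest_one_vs_rest",
    "bh_adjust",
    "de_one_vs_rest",
]

PSEUDOCOUNT = 1e-9
VARIANCE_FLOOR = 1e-12
EXACT_THRESHOLD = 8  # exact Wilcoxon when min group size <= this and no ties


def _cluster_mask(norm, labels, cluster) -> np.ndarray:
    lab = labels.for_cells(norm.cell_ids)
    if str(cluster) not in set(lab):
        raise ValueError(f"cluster {cluster!r} not present among labelled cells")
    return lab == str(cluster)


def log2_fold_change(norm, labels, cluster) -> np.ndarray:
    """Per-gene log2 ratio of mean normalized expression, cluster vs rest."""
    mask = _cluster_mask(norm, labels, cluster)
    if mask.all() or not mask.any():
        raise ValueError("both the cluster and its complement must be non-empty")
    expr = np.expm1(norm.values)
    mean_in = expr[:, mask].mean(axis=1)
    mean_out = expr[:, ~mask].mean(axis=1)
    return np.log2((mean_in + PSEUDOCOUNT) / (mean_out + PSEUDOCOUNT))


def _tie_term_per_gene(x: np.ndarray) -> np.ndarray:
    """Sum of t^3 - t over tied groups, per row of ``x`` (genes x cells)."""
    xs = np.sort(x, axis=1)
    g, c = xs.shape
    starts = np.ones((g, c), dtype=bool)
    starts[:, 1:] = xs[:, 1:] != xs[:, :-1]
    idx = np.flatnonzero(starts.ravel())
    run = np.diff(np.append(idx, g * c)).astype(float)
    return np.bincount(idx // c, weights=run**3 - run, minlength=g)


def _exact_u_pmf(n1: int, n2: int) -> np.ndarray:
    """Null pmf of the Mann-Whitney U statistic via the q-binomial recurrence."""
    m, n = sorted((int(n1), int(n2)))
    u_max = m * n
    poly = np.zeros(u_max + 1)
    poly[0] = 1.0
    for i in range(1, m + 1):
        nxt = poly.copy()
        if n + i <= u_max:
            nxt[n + i :] -= poly[: u_max + 1 - (n + i)]
        for s in range(i, u_max + 1):  # divide by (1 - q^i)
            nxt[s] += nxt[s - i]
        poly = nxt
    return poly / poly.sum()


def wilcoxon_one_vs_rest(norm, labels, cluster):
    """Two-sided Mann-Whitney U per gene, cluster vs rest.

    Returns
    -------
    (u, p) : per-gene U statistic for the cluster group and two-sided p-value.
    """
    mask = _cluster_mask(norm, labels, cluster)
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty for the rank-sum test")
    x = norm.values
    ranks = stats.rankdata(x, axis=1)
    r1 = ranks[:, mask].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2

    tie_term = _tie_term_per_gene(x)
    has_ties = tie_term > 0
    p = np.ones(x.shape[0])

    mu = n1 * n2 / 2.0
    var = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    approx = np.ones_like(p, dtype=bool)

    if min(n1, n2) <= EXACT_THRESHOLD and not has_ties.all():
        exact = ~has_ties
        pmf = _exact_u_pmf(n1, n2)
        cdf = np.cumsum(pmf)
        u_lo = np.minimum(u1[exact], n1 * n2 - u1[exact]).astype(int)
        p[exact] = np.minimum(2.0 * cdf[u_lo], 1.0)
        approx = has_ties.copy()

    if approx.any():
        sd = np.sqrt(var[approx])
        z = np.zeros(int(approx.sum()))
        ok = sd > 0  # sd == 0 means all values tied -> p = 1
        z[ok] = np.maximum(np.abs(u1[approx][ok] - mu) - 0.5, 0.0) / sd[ok]
        p[approx] = np.where(ok, np.minimum(2.0 * stats.norm.sf(z), 1.0), 1.0)
    return u1, p


def ttest_one_vs_rest(norm, labels, cluster):
    """Welch two-sided t-test per gene, cluster vs rest."""
    mask = _cluster_mask(norm, labels, cluster)
    n1, n2 = int(mask.sum()), int((~mask).sum())
    g = norm.values.shape[0]
    if n1 < 2 or n2 < 2:
        warnings.warn("a group has fewer than 2 cells; t-test degenerate, p set to 1")
        return np.zeros(g), np.ones(g)
    a, b = norm.values[:, mask], norm.values[:, ~mask]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = np.maximum(a.var(axis=1, ddof=1), VARIANCE_FLOOR)
    v2 = np.maximum(b.var(axis=1, ddof=1), VARIANCE_FLOOR)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.minimum(p, 1.0)


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_raw must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def de_one_vs_rest(norm, labels, method: str = "wilcoxon") -> pd.DataFrame:
    """Full one-vs-rest DE table over every cluster.

    Returns a tidy frame with columns ``cluster, gene, lfc, p_raw, p_adj,
    test_name``; p-values are BH-adjusted within each cluster across genes.
    """
    tests = {"wilcoxon": wilcoxon_one_vs_rest, "ttest": ttest_one_vs_rest}
    if method not in tests:
        raise ValueError(f"unknown DE method {method!r}; expected one of {sorted(tests)}")
    frames = []
    for cluster in labels.cluster_names:
        lfc = log2_fold_change(norm, labels, cluster)
        _, p_raw = tests[method](norm, labels, cluster)
        frames.append(
            pd.DataFrame(
                {
                    "cluster": cluster,
                    "gene": norm.gene_ids,
                    "lfc": lfc,
                    "p_raw": p_raw,
                    "p_adj": bh_adjust(p_raw),
                    "test_name": method,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
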