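# Methods

## Model

`markerclimb` selects marker genes for a target cluster by maximizing, over
binary selection vectors x on a candidate pool of n genes,

    F(x) = λ1·c1(x) − λ2·R(x) − λ3·S(x)

with

- c1(x) = Σ_g x_g·score_g, where score_g = log2((DEF_t(g)+ε)/(mean_{c≠t} DEF_c(g)+ε))
  and DEF_c(g) is the absolute one-vs-rest log2 fold change of gene g in
  cluster c. The score is deliberately *relative*: it compares the target
  cluster's DE strength to the gene's DE strength everywhere else, so a gene
  that is differential in many clusters is down-weighted even if its target
  fold change is large.
- R(x) = 2·Σ_{g1<g2} x_{g1}x_{g2}·sim(g1,g2) / (S(S−1)+1), the pair-count-
  normalized redundancy, with sim the cosine similarity between the two
  genes' log-normalized expression profiles taken over **all** cells (not
  cluster means). The +1 in the denominator keeps R defined for S ≤ 1, where
  it is 0.
- S(x) = Σ_g x_g, the panel size.

Two modes: *constrained* fixes S = k and restricts moves to swaps (one gene
out, one in); *unconstrained* flips bits freely and λ3 controls the size.
In constrained mode the λ3 term is a constant offset; it is still included
in F for consistency, with default λ3 = 0 there.

## Pipeline

1. **Preprocessing.** Genes expressed (count > 0) in fewer than `min_cells`
   cells are removed (default 3); each cell is scaled to `target_sum` total
   counts (default 10⁴) and log1p-transformed (natural log). Cells with zero
   total counts are dropped with a warning rather than erroring. Gene
   filtering happens once, globally, not per target cluster.
2. **Differential expression.** For every cluster, one-vs-rest log2 fold
   changes on the normalized (expm1) scale with pseudocount ε = 10⁻⁹, plus a
   two-sided test: Wilcoxon rank-sum (default) or Welch t. P-values are
   Benjamini–Hochberg-adjusted per cluster across genes. Both tests and the
   BH step-up are implemented in this package and cross-checked in the test
   suite against independent enumeration/scipy/statsmodels oracles.
   - Wilcoxon: exact null distribution (q-binomial recurrence) when the
     smaller group has ≤ 8 cells and the gene has no ties; otherwise
     tie-corrected normal approximation with continuity correction. Two-sided
     p = 2·P(U ≤ min(U, n1n2−U)), capped at 1.
   - Welch t: Welch–Satterthwaite degrees of freedom; per-group variance
     floored at 10⁻¹² so constant groups stay finite. A group with fewer
     than two cells degrades to p = 1 with a warning.
3. **Candidate pool.** Genes with p_adj ≤ α (default 0.05) in the target
   cluster, ranked by descending log2 fold change (gene id breaks ties),
   truncated to `n_pool` (default 50). If fewer than two genes pass, the
   filter falls back to the top-`n_pool` by fold change with a warning. The
   pool is the optimizer's whole search space; genes outside it can never be
   selected.
4. **Optimization.** ε-greedy stochastic hill climbing: at iteration t, with
   probability ε(t) = ε0·exp(−decay·t) a uniformly random neighbor is
   accepted (exploration); otherwise a batch of neighbors is evaluated and
   the best is taken only on strict improvement. The *best-ever* state is
   tracked separately and returned, so exploration can never lose the
   incumbent. A restart stops after `patience` iterations without best-ever
   improvement or at `max_iters`; the best state over all restarts wins.
   Restart r uses generator seed `seed + r`, making runs exactly
   reproducible. When the pool is no larger than the neighbor batch, all
   single-flip (or, constrained, all swap) neighbors are enumerated in index
   order, which also makes tie-breaking deterministic (lowest-index flip
   wins via first-argmax).

## Defaults and why

| parameter | default | meaning |
|---|---|---|
| λ1, λ2 | 0.9, 0.1 | recommended weighting of score vs redundancy |
| λ3 | 0.05 unconstrained / 0 constrained | panel-size pressure |
| min_cells | 3 | conventional low-expression gene filter |
| target_sum | 10⁴ | conventional per-cell library target |
| n_pool, α | 50, 0.05 | candidate pool size / significance gate |
| ε0, decay | 0.3, 0.01 | exploration schedule (unitless, per iteration) |
| patience, max_iters | 50, 1000 | stagnation stop / hard cap |
| neighbors_per_step | min(pool, 20) | neighbor batch per greedy step |
| restarts | 5 | independent seeded restarts |
| n_flips | 2 | max bits flipped per unconstrained move |

The loop constants are chosen for desk-scale robustness: on 10-gene random
instances the climber with 10 restarts matches exhaustive enumeration
essentially always (the acceptance script measures this), and on 50-gene
pools a run takes well under a second.

## Synthetic data

`simulate_counts` draws a genes × cells negative-binomial count matrix:
gene g in a cell of cluster c has mean
μ = baseline_mean · libfactor(cell) · 2^E_gc, where E_gc is `log2_effect`
for c's own planted markers, `overlap · log2_effect` for the markers of the
designated neighbor cluster ((c+1) mod K — a minimal, testable notion of
overlapping clusters), and 0 otherwise. Counts are NB with size
(dispersion) θ, var = μ + μ²/θ; library factors are log-normal(0, σ);
cells sit in contiguous equal blocks (a size vector can override). Defaults:
2000 genes, 5 × 300 cells, 10 markers/cluster, log2 effect 4, baseline mean
1.0 count, θ = 2.0 (strongly overdispersed, as UMI data typically is),
σ = 0.3. Marker sets are disjoint across clusters and returned as ground
truth for precision/recall scoring.

What the generator does **not** emulate: dropout beyond NB sparsity, batch
effects, doublets, gene–gene correlation within a cluster beyond shared
cluster means, or spatial structure. Tests passing on this generator
therefore certify the selection machinery and its statistics, not robustness
to those real-data artifacts.

## Evaluation metrics

- *Log-ratio difference*: per selected gene, log2 of mean normalized
  expression in the target cluster vs outside (pseudocount ε); a method is
  summarized by the median over its selected genes. Higher is better.
- *Median cosine*: per cluster, the mean log-normalized expression vector
  over the selected genes; the metric is the median cosine between the
  target's vector and each other cluster's. Lower is better; it is 0 exactly
  when the selection is expressed nowhere outside the target. Zero vectors
  get cosine 0 by convention.
- *Ranking*: methods are ranked per dataset on the medians (ties share the
  mean rank) and summarized by mean rank and the standard deviation of the
  medians across datasets.

The aggregation order (median over genes for log-ratio, over other clusters
for cosine) is this package's operationalization of the two prose-defined
metrics.

## Numerical choices

- Pseudocount ε = 10⁻⁹ wherever a log ratio could hit 0/0 (fold changes,
  marker scores, metrics); an all-zero gene gets lfc = 0 by cancellation.
- Cosine similarities are clipped to [0, 1] (profiles are non-negative, so
  true values lie there; clipping removes float noise); zero-norm profiles
  get similarity 0 to others and 1 to themselves.
- Brute-force enumeration breaks objective ties toward the lexicographically
  smallest selection vector, making the oracle deterministic.
- Natural log for normalization, log base 2 for fold changes and scores.

## Known limitations

- The marker score is a ratio of noisy DE magnitudes. For genes with weak
  true DE everywhere, the denominator (mean |lfc| in other clusters) can be
  close to zero by chance, inflating the score — so borderline-significant
  noise genes occasionally outscore genuine markers. On the default
  synthetic conditions this caps planted-marker recovery precision slightly
  below ideal (the acceptance script reports the measured value). A stricter
  pool α or a larger pool of genuinely DE genes mitigates it on real data.
- One-vs-rest fold changes dilute: with K clusters, a perfectly exclusive
  marker still shows substantial |lfc| in *other* clusters' one-vs-rest
  tests (the target cluster sits in their "rest"), which compresses the
  score's dynamic range as K shrinks.
- When marker effects leak heavily between neighboring clusters
  (overlap → 1), target and neighbor DE factors converge and the score loses
  its discrimination — recovery degrades sharply, which the overlapping-
  regime acceptance check measures deliberately. At mild overlap the effect
  on precision is non-monotone at these sample sizes: leakage also pushes
  borderline null genes out of the candidate pool.
- Hill climbing is a heuristic; optimality is verified against exhaustive
  enumeration only at small pool sizes. For default pools (50 genes) the
  restarts and exploration schedule make misses rare but not impossible.
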