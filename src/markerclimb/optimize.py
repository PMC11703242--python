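"""Stochastic hill climbing over binary gene-selection vectors.

The objective balances three terms over a selection vector x in {0,1}^n:

    F(x) = lambda1 * c1(x) - lambda2 * R(x) - lambda3 * S(x)

where c1 is the marker-score sum over selected genes, R is the pair-count-
normalized sum of cosine similarities among selected genes (redundancy), and
S is the number of selected genes (sparsity). Constrained mode keeps S fixed
at k via swap moves; unconstrained mode flips bits freely and lets lambda3
govern the set size. Exploration is epsilon-greedy with an exponentially
decaying rate, and the returned solution is always the best state ever
visited, never the last one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelectionState",
    "ObjectiveConfig",
    "OptimizerParams",
    "HillClimbResult",
    "objective_c1",
    "objective_c2",
    "objective_c3",
    "evaluate_objective",
    "neighbors_unconstrained",
    "neighbors_constrained",
    "hill_climb",
    "brute_force_optimum",
]

SelectionState = np.ndarray  # binary vector aligned to the candidate pool


@dataclass(frozen=True)
class ObjectiveConfig:
    """Weights and mode of the selection objective.

    lambda3 defaults to 0.05 in unconstrained mode (it controls the set size
    there) and to 0 in constrained mode, where the set size is fixed and the
    sparsity term is a constant offset.
    """

    lambda1: float = 0.9
    lambda2: float = 0.1
    lambda3: float | None = None
    mode: str = "unconstrained"
    k: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("constrained", "unconstrained"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if min(self.lambda1, self.lambda2) < 0:
            raise ValueError("lambda weights must be non-negative")
        if self.lambda3 is not None and self.lambda3 < 0:
            raise ValueError("lambda weights must be non-negative")
        if self.mode == "constrained":
            if self.k is None or self.k < 2:
                raise ValueError("constrained mode requires k >= 2")
        if self.lambda3 is None:
            object.__setattr__(self, "lambda3", 0.0 if self.mode == "constrained" else 0.05)

    def validate_pool(self, n: int) -> None:
        if self.mode == "constrained" and not 2 <= self.k <= n:
            raise ValueError(f"constrained k={self.k} must satisfy 2 <= k <= pool size {n}")


@dataclass(frozen=True)
class OptimizerParams:
    """Loop constants for the stochastic hill climber.

    ``epsilon0`` and ``decay`` set the exploration schedule
    eps(t) = epsilon0 * exp(-decay * t); ``patience`` stops a restart after
    that many iterations without a best-ever improvement.
    """

    epsilon0: float = 0.3
    decay: float = 0.01
    patience: int = 50
    max_iters: int = 1000
    neighbors_per_step: int | None = None  # default min(pool size, 20)
    restarts: int = 5
    n_flips: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.epsilon0 <= 1:
            raise ValueError("epsilon0 must lie in [0, 1]")
        for name in ("decay", "patience", "max_iters", "restarts", "n_flips"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.neighbors_per_step is not None and self.neighbors_per_step < 1:
            raise ValueError("neighbors_per_step must be positive")


@dataclass
class HillClimbResult:
    x: SelectionState
    objective: float
    trace: pd.DataFrame = field(repr=False)


def _check_aligned(x: np.ndarray, n: int) -> np.ndarray:
    x = np.asarray(x)
    if x.shape != (n,):
        raise ValueError(f"selection vector of length {x.shape} misaligned with pool size {n}")
    return x.astype(float)


def objective_c1(x: SelectionState, scores: np.ndarray) -> float:
    """Sum of marker scores over selected genes."""
    scores = np.asarray(scores, dtype=float)
    return float(_check_aligned(x, scores.size) @ scores)


def objective_c2(x: SelectionState, sim: np.ndarray) -> float:
    """Redundancy magnitude R(x) = 2*sum_{g1<g2} x x sim / (S(S-1)+1)."""
    sim = np.asarray(sim, dtype=float)
    xf = _check_aligned(x, sim.shape[0])
    s = xf.sum()
    pair2 = xf @ sim @ xf - xf @ np.diag(sim)  # = 2 * sum over unordered pairs
    return float(pair2 / (s * (s - 1) + 1))


def objective_c3(x: SelectionState) -> float:
    """Selected-set size S(x)."""
    return float(np.asarray(x).sum())


def evaluate_objective(x: SelectionState, scores, sim, cfg: ObjectiveConfig) -> float:
    """F(x) = lambda1*c1 - lambda2*R - lambda3*S."""
    return (
        cfg.lambda1 * objective_c1(x, scores)
        - cfg.lambda2 * objective_c2(x, sim)
        - cfg.lambda3 * objective_c3(x)
    )


def _evaluate_batch(states: np.ndarray, scores, sim, cfg: ObjectiveConfig) -> np.ndarray:
    """Vectorized F over a (m, n) stack of selection vectors."""
    x = states.astype(float)
    s = x.sum(axis=1)
    c1 = x @ scores
    quad = np.einsum("ij,jk,ik->i", x, sim, x)
    pair2 = quad - x @ np.diag(sim)
    r = pair2 / (s * (s - 1) + 1)
    return cfg.lambda1 * c1 - cfg.lambda2 * r - cfg.lambda3 * s


def neighbors_unconstrained(
    x: SelectionState, n_flips: int, rng: np.random.Generator, n_neighbors: int | None = None
) -> np.ndarray:
    """Bit-flip neighbors of ``x`` as a stacked (m, n) array.

    When the pool is no larger than ``n_neighbors`` every single-flip
    neighbor is included (in index order); remaining slots, and the whole
    batch for larger pools, are random flips of 1..n_flips distinct positions.
    """
    if n_flips < 1:
        raise ValueError("n_flips must be >= 1")
    n = x.size
    if n_neighbors is None:
        n_neighbors = min(n, 20)
    out = []
    if n <= n_neighbors:
        eye = np.eye(n, dtype=x.dtype)
        out.append(np.abs(x[None, :] - eye))  # all single flips, index order
        n_random = n_neighbors - n
    else:
        n_random = n_neighbors
    for _ in range(n_random):
        size = int(rng.integers(1, n_flips + 1))
        pos = rng.choice(n, size=min(size, n), replace=False)
        nb = x.copy()
        nb[pos] = 1 - nb[pos]
        out.append(nb[None, :])
    return np.concatenate(out, axis=0)


def neighbors_constrained(
    x: SelectionState, rng: np.random.Generator, n_neighbors: int | None = None
) -> np.ndarray:
    """Swap neighbors of ``x`` (one selected bit off, one unselected bit on).

    All swaps are enumerated (deterministic order) when there are no more
    than ``n_neighbors`` of them; otherwise that many are sampled.
    """
    ones = np.flatnonzero(x == 1)
    zeros = np.flatnonzero(x == 0)
    if ones.size == 0 or zeros.size == 0:
        raise ValueError("constrained neighborhood undefined for empty or full selection")
    if n_neighbors is None:
        n_neighbors = min(x.size, 20)
    n_swaps = ones.size * zeros.size
    out = []
    if n_swaps <= n_neighbors:
        pairs = [(i, j) for i in ones for j in zeros]
    else:
        pick = rng.integers(0, n_swaps, size=n_neighbors)
        pairs = [(ones[p // zeros.size], zeros[p % zeros.size]) for p in pick]
    for i, j in pairs:
        nb = x.copy()
        nb[i], nb[j] = 0, 1
        out.append(nb)
    return np.stack(out)


def _init_state(n: int, cfg: ObjectiveConfig, rng: np.random.Generator) -> SelectionState:
    if cfg.mode == "constrained":
        x = np.zeros(n, dtype=np.int8)
        x[rng.choice(n, size=cfg.k, replace=False)] = 1
        return x
    return rng.integers(0, 2, size=n).astype(np.int8)


def hill_climb(scores, sim, cfg: ObjectiveConfig, params: OptimizerParams | None = None) -> HillClimbResult:
    """Maximize F by epsilon-greedy stochastic hill climbing with restarts.

    Each restart r runs from its own seeded generator (seed + r). At
    iteration t a uniformly random neighbor is accepted with probability
    eps(t) (exploration); otherwise the best of a batch of neighbors is taken
    if it strictly improves the current objective. A restart stops after
    ``patience`` iterations without improving the best state ever seen.
    """
    scores = np.asarray(scores, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if params is None:
        params = OptimizerParams()
    n = scores.size
    if n < 2:
        raise ValueError("pool size must be >= 2")
    if sim.shape != (n, n):
        raise ValueError("similarity matrix misaligned with scores")
    cfg.validate_pool(n)
    if cfg.mode == "constrained" and not 2 <= cfg.k <= n - 1:
        raise ValueError(f"constrained k={cfg.k} needs 2 <= k <= pool size - 1 for swap moves")
    m = params.neighbors_per_step or min(n, 20)

    best_x_all, best_f_all = None, -np.inf
    rows = []
    for r in range(params.restarts):
        rng = np.random.default_rng(params.seed + r)
        x = _init_state(n, cfg, rng)
        f_cur = evaluate_objective(x, scores, sim, cfg)
        best_x, best_f = x.copy(), f_cur
        stall = 0
        for t in range(params.max_iters):
            eps = params.epsilon0 * np.exp(-params.decay * t)
            if cfg.mode == "constrained":
                nbrs = neighbors_constrained(x, rng, n_neighbors=m)
            else:
                nbrs = neighbors_unconstrained(x, params.n_flips, rng, n_neighbors=m)
            if rng.random() < eps:
                x = nbrs[rng.integers(0, nbrs.shape[0])].copy()
                f_cur = evaluate_objective(x, scores, sim, cfg)
            else:
                f_nbrs = _evaluate_batch(nbrs, scores, sim, cfg)
                j = int(np.argmax(f_nbrs))  # first max -> lowest-index flip wins ties
                if f_nbrs[j] > f_cur:
                    x = nbrs[j].copy()
                    f_cur = float(f_nbrs[j])
            if cfg.mode == "constrained":
                assert int(x.sum()) == cfg.k, "swap move violated the size constraint"
            if f_cur > best_f:
                best_f, best_x = f_cur, x.copy()
                stall = 0
            else:
                stall += 1
            rows.append((r, t, f_cur, best_f, int(x.sum()), eps))
            if stall >= params.patience:
                break
        if best_f > best_f_all:
            best_f_all, best_x_all = best_f, best_x
    trace = pd.DataFrame(rows, columns=["restart", "iter", "current_F", "best_F", "n_selected", "epsilon"])
    return HillClimbResult(x=best_x_all.astype(np.int8), objective=float(best_f_all), trace=trace)


def brute_force_optimum(scores, sim, cfg: ObjectiveConfig):
    """Exhaustive argmax of F for small pools; the optimizer's test oracle.

    Ties are broken toward the lexicographically smallest selection vector.
    """
    scores = np.asarray(scores, dtype=float)
    sim = np.asarray(sim, dtype=float)
    n = scores.size
    cfg.validate_pool(n)
    if cfg.mode == "constrained":
        from math import comb

        if comb(n, cfg.k) > 10**6:
            raise ValueError("search space too large for brute force; use hill_climb")
        states = (tuple(1 if i in sel else 0 for i in range(n))
                  for sel in itertools.combinations(range(n), cfg.k))
    else:
        if n > 20:
            raise ValueError("pool too large for brute force; use hill_climb")
        states = itertools.product((0, 1), repeat=n)
    best_x, best_f = None, -np.inf
    for state in states:
        x = np.array(state, dtype=np.int8)
        f = evaluate_objective(x, scores, sim, cfg)
        if f > best_f or (f == best_f and best_x is not None and state < tuple(best_x)):
            best_f, best_x = f, x
    return best_x, float(best_f)
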