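import numpy as np
import pytest

from markerclimb import (
    ObjectiveConfig,
    OptimizerParams,
    brute_force_optimum,
    evaluate_objective,
    hill_climb,
    neighbors_constrained,
    neighbors_unconstrained,
    objective_c1,
    objective_c2,
    objective_c3,
)


def random_instance(rng, n=10):
    scores = rng.normal(size=n)
    sim = rng.uniform(size=(n, n))
    sim = (sim + sim.T) / 2
    np.fill_diagonal(sim, 1.0)
    return scores, sim


class TestObjectiveTerms:
    def test_c1_hand_sum(self):
        assert objective_c1([1, 0, 1], [2.0, 1.0, 0.5]) == pytest.approx(2.5, abs=1e-6)

    def test_c1_empty_and_singleton(self):
        scores = [2.0, 1.0, 0.5]
        assert objective_c1([0, 0, 0], scores) == 0.0
        assert objective_c1([0, 1, 0], scores) == pytest.approx(1.0)

    def test_c2_pairless_selections_are_zero(self):
        sim = np.eye(3)
        assert objective_c2([0, 0, 0], sim) == 0.0
        assert objective_c2([1, 0, 0], sim) == 0.0

    def test_c2_two_genes_hand_value(self):
        sim = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert objective_c2([1, 1], sim) == pytest.approx(1 / 3, abs=1e-6)

    def test_c2_three_genes_all_similar(self):
        sim = np.ones((3, 3))
        assert objective_c2([1, 1, 1], sim) == pytest.approx(6 / 7, abs=1e-6)

    def test_c3_counts_selection(self):
        assert objective_c3([0, 0]) == 0.0
        assert objective_c3([1, 1, 1]) == 3.0

    def test_objective_hand_value(self):
        scores = [2.0, 0.8]
        sim = np.array([[1.0, 0.2], [0.2, 1.0]])
        cfg = ObjectiveConfig(lambda1=0.9, lambda2=0.1, lambda3=0.05)
        assert evaluate_objective([1, 1], scores, sim, cfg) == pytest.approx(2.406667, abs=1e-6)

    def test_degenerate_weights_reduce_to_c1(self):
        rng = np.random.default_rng(0)
        scores, sim = random_instance(rng, 6)
        cfg = ObjectiveConfig(lambda1=0.7, lambda2=0.0, lambda3=0.0)
        x = rng.integers(0, 2, 6)
        assert evaluate_objective(x, scores, sim, cfg) == pytest.approx(0.7 * objective_c1(x, scores))

    def test_empty_selection_is_zero(self):
        rng = np.random.default_rng(1)
        scores, sim = random_instance(rng, 5)
        assert evaluate_objective(np.zeros(5), scores, sim, ObjectiveConfig()) == 0.0

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            objective_c1([1, 0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="misaligned"):
            objective_c2([1, 0], np.eye(3))


class TestNeighbors:
    def test_unconstrained_exhaustive_single_flips(self):
        rng = np.random.default_rng(0)
        x = np.array([1, 0, 0], dtype=np.int8)
        nbrs = neighbors_unconstrained(x, n_flips=1, rng=rng, n_neighbors=3)
        got = {tuple(n) for n in nbrs.astype(int)}
        assert got == {(0, 0, 0), (1, 1, 0), (1, 0, 1)}

    def test_full_flip_reaches_complement(self):
        rng = np.random.default_rng(0)
        x = np.array([1, 0, 1], dtype=np.int8)
        seen = set()
        for _ in range(200):
            for n in neighbors_unconstrained(x, n_flips=3, rng=rng, n_neighbors=8):
                seen.add(tuple(n.astype(int)))
        assert (0, 1, 0) in seen  # complement reachable

    def test_every_neighbor_differs(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 12).astype(np.int8)
        nbrs = neighbors_unconstrained(x, n_flips=2, rng=rng, n_neighbors=30)
        assert all((n != x).any() for n in nbrs)

    def test_constrained_swap_enumeration(self):
        rng = np.random.default_rng(0)
        x = np.array([1, 1, 0, 0], dtype=np.int8)
        nbrs = neighbors_constrained(x, rng, n_neighbors=10)
        assert len(nbrs) == 4  # 2 ones x 2 zeros
        assert all(n.sum() == 2 for n in nbrs)

    def test_constrained_k_one_below_pool(self):
        rng = np.random.default_rng(0)
        x = np.array([1, 1, 0], dtype=np.int8)
        nbrs = neighbors_constrained(x, rng, n_neighbors=10)
        assert len(nbrs) == 2

    def test_constrained_full_selection_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="empty or full"):
            neighbors_constrained(np.ones(3, dtype=np.int8), rng)


class TestBruteForce:
    def test_single_positive_gene_selected(self):
        scores = np.array([1.5, -2.0])
        sim = np.eye(2)
        x, f = brute_force_optimum(scores, sim, ObjectiveConfig(lambda1=1.0, lambda2=0.0, lambda3=0.0))
        assert list(x) == [1, 0]
        assert f == pytest.approx(1.5)

    def test_constrained_avoids_similar_pair(self):
        scores = np.ones(4)
        sim = np.eye(4)
        sim[0, 1] = sim[1, 0] = 0.95  # one highly redundant pair
        cfg = ObjectiveConfig(mode="constrained", k=2)
        x, _ = brute_force_optimum(scores, sim, cfg)
        assert not (x[0] == 1 and x[1] == 1)

    def test_oracle_value_self_consistent(self):
        rng = np.random.default_rng(4)
        scores, sim = random_instance(rng, 8)
        cfg = ObjectiveConfig()
        x, f = brute_force_optimum(scores, sim, cfg)
        assert f == pytest.approx(evaluate_objective(x, scores, sim, cfg), rel=1e-12)

    def test_too_large_pool_rejected(self):
        with pytest.raises(ValueError, match="brute force"):
            brute_force_optimum(np.zeros(25), np.eye(25), ObjectiveConfig())


class TestHillClimb:
    def test_constrained_topk_when_only_scores_matter(self):
        scores = np.array([3.0, 2.0, 1.0, 0.0])
        sim = np.eye(4)
        cfg = ObjectiveConfig(lambda1=0.9, lambda2=0.0, lambda3=0.0, mode="constrained", k=2)
        res = hill_climb(scores, sim, cfg, OptimizerParams(seed=0))
        assert list(res.x) == [1, 1, 0, 0]
        assert res.objective == pytest.approx(0.9 * 5.0)

    def test_unconstrained_all_negative_scores_empty_optimum(self):
        rng = np.random.default_rng(0)
        scores = -np.abs(rng.normal(size=8)) - 0.1
        _, sim = random_instance(rng, 8)
        cfg = ObjectiveConfig(lambda3=0.05)
        res = hill_climb(scores, sim, cfg, OptimizerParams(seed=1, restarts=5))
        assert res.objective == pytest.approx(0.0, abs=1e-12)
        assert res.x.sum() == 0

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(6)
        scores, sim = random_instance(rng, 12)
        cfg = ObjectiveConfig()
        params = OptimizerParams(seed=123, restarts=3, max_iters=200)
        r1 = hill_climb(scores, sim, cfg, params)
        r2 = hill_climb(scores, sim, cfg, params)
        assert np.array_equal(r1.x, r2.x)
        assert r1.objective == r2.objective
        assert r1.trace.equals(r2.trace)

    def test_best_trace_monotone_and_constrained_size_invariant(self):
        rng = np.random.default_rng(8)
        scores, sim = random_instance(rng, 15)
        cfg = ObjectiveConfig(mode="constrained", k=5)
        res = hill_climb(scores, sim, cfg, OptimizerParams(seed=2, restarts=3))
        for _, grp in res.trace.groupby("restart"):
            assert np.all(np.diff(grp["best_F"]) >= -1e-12)
        assert (res.trace["n_selected"] == 5).all()
        assert res.x.sum() == 5

    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(10)
        hits = 0
        for i in range(20):
            scores, sim = random_instance(rng, 10)
            cfg = ObjectiveConfig()
            x_opt, f_opt = brute_force_optimum(scores, sim, cfg)
            res = hill_climb(scores, sim, cfg, OptimizerParams(seed=1000 + i, restarts=10, max_iters=500))
            assert res.objective <= f_opt + 1e-9
            hits += res.objective >= f_opt - 1e-9
        assert hits >= 19

    def test_invalid_configs_rejected_before_iteration(self):
        with pytest.raises(ValueError):
            ObjectiveConfig(mode="constrained")  # k missing
        with pytest.raises(ValueError):
            ObjectiveConfig(lambda1=-0.1)
        with pytest.raises(ValueError):
            OptimizerParams(epsilon0=1.5)
        scores, sim = np.ones(4), np.eye(4)
        with pytest.raises(ValueError, match="k"):
            hill_climb(scores, sim, ObjectiveConfig(mode="constrained", k=4), OptimizerParams())
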