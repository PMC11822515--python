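from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from wormqsar.data import DescriptorMatrix
from wormqsar.ga import (GAConfig, Individual, apply_operators, crowding_distance,
                         evaluate_individual, fast_non_dominated_sort, init_population,
                         nsga2_select, penalty, run_ga)
from wormqsar.gbt import Dimension, SearchSpace

# Small search space keeps nested tuning cheap in unit tests.
TINY_SPACE = SearchSpace((
    Dimension("shrinkage", 0.05, 0.3, scale="log"),
    Dimension("n_trees", 20, 80, integer=True),
    Dimension("max_depth", 1, 3, integer=True),
))


def _random_population(rng, n, n_objectives=5):
    pop = []
    for _ in range(n):
        ind = Individual(mask=np.array([True]))
        obj = rng.random(n_objectives)
        ind.objectives = (-obj[0], -obj[1], obj[2], obj[3], -obj[4])
        pop.append(ind)
    return pop


def brute_force_select(population, k):
    """Independent NSGA-II oracle: exhaustive domination ranks + crowding."""
    vectors = [ind.minimization_vector() for ind in population]
    n = len(vectors)

    def dominates(a, b):
        return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))

    ranks = {}
    remaining = set(range(n))
    rank = 0
    while remaining:
        front = {i for i in remaining
                 if not any(dominates(vectors[j], vectors[i])
                            for j in remaining if j != i)}
        for i in front:
            ranks[i] = rank
        remaining -= front
        rank += 1

    selected = []
    for r in range(rank):
        front = sorted(i for i in range(n) if ranks[i] == r)
        if len(selected) + len(front) <= k:
            selected.extend(front)
        else:
            vecs = np.array([vectors[i] for i in front])
            m = vecs.shape[1]
            cd = np.zeros(len(front))
            if len(front) <= 2:
                cd[:] = np.inf
            else:
                for obj in range(m):
                    order = np.argsort(vecs[:, obj], kind="stable")
                    cd[order[0]] = cd[order[-1]] = np.inf
                    span = vecs[order[-1], obj] - vecs[order[0], obj]
                    if span == 0:
                        continue
                    for pos in range(1, len(front) - 1):
                        cd[order[pos]] += (vecs[order[pos + 1], obj]
                                           - vecs[order[pos - 1], obj]) / span
            by_crowding = sorted(range(len(front)), key=lambda i: (-cd[i], front[i]))
            selected.extend(front[i] for i in by_crowding[: k - len(selected)])
        if len(selected) == k:
            break
    return selected


class TestPenalty:
    @pytest.mark.parametrize("d,expected", [(1, 0.5), (4, 0.2), (9, 0.1)])
    def test_closed_form(self, d, expected):
        assert penalty(d) == pytest.approx(expected)

    def test_strictly_decreasing(self):
        values = [penalty(d) for d in range(1, 2200)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_empty_mask_forbidden(self):
        with pytest.raises(ValueError):
            penalty(0)


class TestInitPopulation:
    def test_size_and_nonempty_masks(self):
        pop = init_population(300, GAConfig(population_size=50, seed=0))
        assert len(pop) == 50
        assert all(ind.n_selected >= 1 for ind in pop)

    def test_expected_density_matches_target(self):
        config = GAConfig(population_size=400, init_bits=10, seed=1)
        pop = init_population(300, config)
        mean_bits = np.mean([ind.n_selected for ind in pop])
        assert abs(mean_bits - 10) < 1.0

    def test_seed_determinism(self):
        a = init_population(100, GAConfig(population_size=20, seed=5))
        b = init_population(100, GAConfig(population_size=20, seed=5))
        assert all(np.array_equal(x.mask, y.mask) for x, y in zip(a, b))


class TestApplyOperators:
    def _population(self, n=10, n_desc=40, seed=0):
        rng = np.random.default_rng(seed)
        return [Individual(mask=rng.random(n_desc) < 0.3) for _ in range(n)]

    def test_partition_counts_with_odd_crossover(self):
        # n=10: round(5)=5 -> 4 crossed (2 pairs), 1 moved to unchanged,
        # 1 mutated, 5 untouched masks in total.
        pop = self._population(10)
        config = GAConfig(population_size=10, crossover_swap_prob=0.5,
                          mutation_bitflip_prob=0.5, seed=2)
        rng = np.random.default_rng(0)
        out = apply_operators(pop, config, rng)
        assert len(out) == 10
        changed = sum(ind.needs_tuning for ind in out)
        assert changed == 5  # 4 crossover participants + 1 mutated

    def test_zero_swap_probability_is_identity(self):
        pop = self._population(8)
        config = GAConfig(population_size=8, crossover_swap_prob=0.0,
                          mutation_bitflip_prob=0.0, seed=3)
        out = apply_operators(pop, config, np.random.default_rng(1))
        assert all(np.array_equal(a.mask, b.mask) for a, b in zip(pop, out))

    def test_full_bitflip_complements_mutated_mask(self):
        pop = self._population(10, seed=4)
        config = GAConfig(population_size=10, crossover_share=0.0,
                          mutation_share=1.0, unchanged_share=0.0,
                          mutation_bitflip_prob=1.0, seed=4)
        out = apply_operators(pop, config, np.random.default_rng(2))
        for before, after in zip(pop, out):
            expected = ~before.mask
            if not expected.any():  # repaired empty mask
                assert after.n_selected == 1
            else:
                assert np.array_equal(after.mask, expected)

    def test_crossover_preserves_multiset_of_genes_per_position(self):
        pop = self._population(8, seed=5)
        config = GAConfig(population_size=8, crossover_share=1.0,
                          mutation_share=0.0, unchanged_share=0.0,
                          crossover_swap_prob=0.7, seed=5)
        out = apply_operators(pop, config, np.random.default_rng(3))
        before = np.sum([ind.mask for ind in pop], axis=0)
        after = np.sum([ind.mask for ind in out], axis=0)
        assert np.array_equal(before, after)

    def test_no_empty_masks_after_operators(self):
        rng = np.random.default_rng(6)
        pop = [Individual(mask=np.zeros(20, dtype=bool)) for _ in range(10)]
        for ind in pop:
            ind.mask[0] = True
        config = GAConfig(population_size=10, mutation_share=1.0, crossover_share=0.0,
                          unchanged_share=0.0, mutation_bitflip_prob=1.0, seed=7)
        out = apply_operators(pop, config, rng)
        assert all(ind.n_selected >= 1 for ind in out)


class TestNsga2:
    def test_dominating_individual_always_selected(self):
        rng = np.random.default_rng(0)
        pop = _random_population(rng, 8)
        hero = Individual(mask=np.array([True]))
        hero.objectives = (1.0, 1.0, 0.0, 0.0, 1.0)  # dominates everything
        selected = nsga2_select(pop + [hero], 3)
        assert any(ind is hero for ind in selected)

    def test_identical_vectors_form_one_front(self):
        pop = _random_population(np.random.default_rng(1), 1) * 6
        fronts = fast_non_dominated_sort(
            np.vstack([ind.minimization_vector() for ind in pop]))
        assert len(fronts) == 1

    def test_matches_brute_force_oracle_across_seeds(self):
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(6, 16))
            k = int(rng.integers(1, n + 1))
            pop = _random_population(rng, n)
            ours = nsga2_select(pop, k)
            oracle = brute_force_select(pop, k)
            assert [pop.index(ind) for ind in ours] == oracle

    def test_k_larger_than_population_rejected(self):
        pop = _random_population(np.random.default_rng(2), 4)
        with pytest.raises(ValueError):
            nsga2_select(pop, 5)

    def test_crowding_boundary_points_infinite(self):
        vecs = np.array([[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]])
        cd = crowding_distance(vecs)
        assert np.isinf(cd[0]) and np.isinf(cd[2])
        assert np.isfinite(cd[1])


def _signal_matrix(n=80, n_desc=12, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = pd.DataFrame(rng.normal(size=(n, n_desc)),
                     columns=[f"d{i}" for i in range(n_desc)])
    X["d0"] = X["d0"] + 1.5 * y
    X.index = pd.Index([f"c{i}" for i in range(n)], name="compound_id")
    return DescriptorMatrix(X, pd.Series(y, index=X.index))


class TestEvaluateIndividual:
    def test_objectives_are_five_finite_values(self):
        m = _signal_matrix()
        ind = Individual(mask=np.array([True] * 3 + [False] * 9))
        out = evaluate_individual(ind, m, generation_seed=1, space=TINY_SPACE,
                                  bayes_iterations=3, cv_folds=3)
        assert len(out.objectives) == 5
        assert np.all(np.isfinite(out.minimization_vector()))
        assert out.tuned_hp is not None
        assert out.objectives[4] == penalty(3)

    def test_informative_mask_beats_noise_mask(self):
        m = _signal_matrix(n=120)
        info = Individual(mask=np.array([True] + [False] * 11))
        noise = Individual(mask=np.array([False, False, True, True] + [False] * 8))
        info = evaluate_individual(info, m, 2, space=TINY_SPACE,
                                   bayes_iterations=3, cv_folds=3)
        noise = evaluate_individual(noise, m, 2, space=TINY_SPACE,
                                    bayes_iterations=3, cv_folds=3)
        assert info.objectives[1] > noise.objectives[1] + 0.2  # MCC_val gap

    def test_empty_mask_rejected(self):
        m = _signal_matrix()
        with pytest.raises(ValueError):
            evaluate_individual(Individual(mask=np.zeros(12, dtype=bool)), m, 0)


class TestRunGa:
    def test_zero_generations_returns_evaluated_initial_population(self):
        m = _signal_matrix()
        config = GAConfig(population_size=4, n_generations=0, bayes_iterations=2,
                          cv_folds=3, init_bits=3, seed=0)
        pop, hof, log = run_ga(m, config, space=TINY_SPACE)
        assert len(pop) == 4
        assert all(ind.objectives is not None for ind in pop)
        assert set(log["generation"]) == {0}
        assert hof.best_specificity is not None

    def test_same_seed_reproduces_hall_of_fame(self):
        m = _signal_matrix()
        config = GAConfig(population_size=4, n_generations=1, bayes_iterations=2,
                          cv_folds=3, init_bits=3, seed=9)
        _, hof1, _ = run_ga(m, config, space=TINY_SPACE)
        _, hof2, _ = run_ga(m, config, space=TINY_SPACE)
        assert np.array_equal(hof1.best_specificity.mask, hof2.best_specificity.mask)
        assert np.array_equal(hof1.best_sensitivity.mask, hof2.best_sensitivity.mask)
        assert hof1.best_specificity.objectives == hof2.best_specificity.objectives

    def test_parsimony_pressure_on_signal_free_data(self):
        # Without signal the penalty objective dominates the evolution, so
        # median mask size must not grow.
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(60, 20)),
                         columns=[f"d{i}" for i in range(20)])
        X.index = pd.Index([f"c{i}" for i in range(60)], name="compound_id")
        m = DescriptorMatrix(X, pd.Series(rng.integers(0, 2, 60), index=X.index))
        config = GAConfig(population_size=8, n_generations=3, bayes_iterations=2,
                          cv_folds=3, init_bits=8, seed=4)
        _, _, log = run_ga(m, config, space=TINY_SPACE)
        medians = log.groupby("generation")["n_selected"].median()
        assert medians.iloc[-1] <= medians.iloc[0]

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GAConfig(crossover_share=0.9, mutation_share=0.9,
                     unchanged_share=0.2).validate()
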