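"""Wrapper feature selection: a five-objective genetic algorithm over
binary descriptor masks with NSGA-II survivor selection.

Each individual is a binary mask over all descriptors. Per generation, 50%
of individuals participate in uniform crossover, 10% in per-bit mutation and
40% are left unchanged (mutually exclusive); the modeling pool is resampled
80/20 into train/validation parts; the training part is randomly
under-sampled to class balance; hyperparameters of operator-modified masks
are re-tuned by the budgeted Bayesian search; and every individual is scored
on five objectives — MCC on train, MCC on validation, Brier score on train,
Brier score on validation, and a parsimony reward P(d) = 1/(1+d) on the mask
size d. Survivors are chosen by fast non-dominated sorting with crowding
distance (NSGA-II) on the canonical minimization vector
(-MCC_train, -MCC_val, BS_train, BS_val, -penalty).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .curation import resample_train_val, under_sample
from .data import DescriptorMatrix, derive_seed
from .gbt import (Hyperparameters, SearchSpace, bayes_optimize, cv_objective,
                  default_search_space, fit_gbt)
from .metrics import MetricReport, evaluate_predictions

log = logging.getLogger(__name__)

OBJECTIVE_NAMES = ("mcc_train", "mcc_val", "bs_train", "bs_val", "penalty")


@dataclass
class Individual:
    mask: np.ndarray  # boolean over all descriptors
    tuned_hp: Hyperparameters | None = None
    objectives: tuple[float, ...] | None = None  # (MCC_tr, MCC_val, BS_tr, BS_val, P)
    train_report: MetricReport | None = None
    val_report: MetricReport | None = None
    needs_tuning: bool = True

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def minimization_vector(self) -> np.ndarray:
        """Canonical all-minimized objective vector for NSGA-II."""
        if self.objectives is None:
            raise ValueError("individual not yet evaluated")
        mcc_tr, mcc_val, bs_tr, bs_val, pen = self.objectives
        return np.array([-mcc_tr, -mcc_val, bs_tr, bs_val, -pen])

    def copy(self) -> "Individual":
        return Individual(mask=self.mask.copy(), tuned_hp=self.tuned_hp,
                          objectives=self.objectives, train_report=self.train_report,
                          val_report=self.val_report, needs_tuning=self.needs_tuning)


@dataclass
class GAConfig:
    population_size: int = 50
    n_generations: int = 20
    crossover_share: float = 0.5
    mutation_share: float = 0.1
    unchanged_share: float = 0.4
    crossover_swap_prob: float = 0.5
    mutation_bitflip_prob: float | None = None  # default 1 / n_descriptors
    init_bits: int = 10
    bayes_iterations: int = 32
    cv_folds: int = 5
    train_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        shares = self.crossover_share + self.mutation_share + self.unchanged_share
        if abs(shares - 1.0) > 1e-9:
            raise ValueError("operator shares must sum to 1")
        if self.population_size < 4:
            raise ValueError("population_size must be at least 4")


def penalty(n_selected: int) -> float:
    """Parsimony score P(d) = 1/(1+d), strictly decreasing in mask size."""
    if n_selected < 1:
        raise ValueError("empty descriptor masks are forbidden")
    return 1.0 / (1.0 + n_selected)


def init_population(n_descriptors: int, config: GAConfig) -> list[Individual]:
    """Seeded random masks with expected density ~init_bits set bits."""
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "ga-init"))
    p = min(1.0, config.init_bits / n_descriptors)
    population = []
    for _ in range(config.population_size):
        mask = rng.random(n_descriptors) < p
        if not mask.any():
            mask[rng.integers(n_descriptors)] = True
        population.append(Individual(mask=mask))
    return population


def apply_operators(population: list[Individual], config: GAConfig,
                    rng: np.random.Generator | None = None) -> list[Individual]:
    """Produce the offspring population via the 50/10/40 operator partition.

    A seeded permutation assigns round(0.5 n) individuals to crossover (in
    pairs; an odd leftover is moved to the unchanged group), round(0.1 n) to
    mutation, and the remainder unchanged. Uniform crossover swaps each gene
    between the pair with ``crossover_swap_prob``; mutation flips each bit
    with ``mutation_bitflip_prob`` (default 1/n_descriptors). Masks emptied
    by an operator are repaired by setting one seeded random bit.
    """
    if len(population) < 2:
        raise ValueError("need at least two individuals")
    if rng is None:
        rng = np.random.default_rng(derive_seed(config.seed, "ga-operators"))
    n = len(population)
    n_desc = population[0].mask.size
    n_cross = round(config.crossover_share * n)
    n_mut = round(config.mutation_share * n)
    if n_cross % 2 == 1:
        log.info("odd crossover count %d: moving one individual to unchanged", n_cross)
        n_cross -= 1
    order = rng.permutation(n)
    cross_idx = order[:n_cross]
    mut_idx = order[n_cross:n_cross + n_mut]

    flip_p = config.mutation_bitflip_prob
    if flip_p is None:
        flip_p = 1.0 / n_desc

    offspring = [ind.copy() for ind in population]
    for ind in offspring:
        ind.needs_tuning = False
    for a, b in zip(cross_idx[0::2], cross_idx[1::2]):
        swap = rng.random(n_desc) < config.crossover_swap_prob
        ma, mb = offspring[a].mask, offspring[b].mask
        ma[swap], mb[swap] = mb[swap].copy(), ma[swap].copy()
        for i in (a, b):
            offspring[i].needs_tuning = True
            offspring[i].objectives = None
    for i in mut_idx:
        flips = rng.random(n_desc) < flip_p
        offspring[i].mask = offspring[i].mask ^ flips
        offspring[i].needs_tuning = True
        offspring[i].objectives = None
    for ind in offspring:
        if not ind.mask.any():
            ind.mask[rng.integers(n_desc)] = True
    return offspring


def evaluate_individual(
    ind: Individual,
    modeling_set: DescriptorMatrix,
    generation_seed: int,
    space: SearchSpace | None = None,
    bayes_iterations: int = 32,
    cv_folds: int = 5,
    train_fraction: float = 0.8,
    retune: bool | None = None,
) -> Individual:
    """Score one mask: resample, under-sample, (re)tune, fit, five objectives.

    The train/validation resample is driven by ``generation_seed`` alone, so
    all individuals of a generation share the same split. A resample that
    leaves the validation part single-class is redrawn with an incremented
    seed (at most 10 attempts).
    """
    if ind.n_selected == 0:
        raise ValueError("cannot evaluate an empty mask")
    if space is None:
        space = default_search_space()
    data = modeling_set.select_descriptors(ind.mask)

    train = val = None
    for attempt in range(10):
        t, v = resample_train_val(data, train_fraction, seed=generation_seed + attempt)
        if v.y.nunique() == 2 and t.y.nunique() == 2:
            train, val = t, v
            break
    if train is None:
        raise RuntimeError("could not draw a train/validation split with both classes "
                           "in each part after 10 attempts")

    if retune is None:
        retune = ind.needs_tuning or ind.tuned_hp is None
    if retune or ind.tuned_hp is None:
        tune_seed = derive_seed(generation_seed, "bayes")
        best_hp, _ = bayes_optimize(
            lambda hp: cv_objective(train, None, hp, k=cv_folds, seed=tune_seed),
            space=space, n_iterations=bayes_iterations, seed=tune_seed,
        )
        ind.tuned_hp = best_hp
        ind.needs_tuning = False

    fit_seed = derive_seed(generation_seed, "fit")
    model = fit_gbt(under_sample(train, fit_seed), ind.tuned_hp, fit_seed)
    train_rep = evaluate_predictions(train.y, model.predict_proba(train))
    val_rep = evaluate_predictions(val.y, model.predict_proba(val))
    ind.train_report, ind.val_report = train_rep, val_rep
    ind.objectives = (train_rep.mcc, val_rep.mcc, train_rep.brier, val_rep.brier,
                      penalty(ind.n_selected))
    if not np.all(np.isfinite(ind.minimization_vector())):
        raise RuntimeError("non-finite objective vector")
    return ind


# ---------------------------------------------------------------------------
# NSGA-II selection


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a <= b) and np.any(a < b))


def fast_non_dominated_sort(vectors: np.ndarray) -> list[list[int]]:
    """Partition indices into Pareto fronts (all objectives minimized)."""
    n = len(vectors)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(vectors[i], vectors[j]):
                dominated_by[i].append(j)
                counts[j] += 1
            elif _dominates(vectors[j], vectors[i]):
                dominated_by[j].append(i)
                counts[i] += 1
    fronts = [[i for i in range(n) if counts[i] == 0]]
    while fronts[-1]:
        nxt = []
        for i in fronts[-1]:
            for j in dominated_by[i]:
                counts[j] -= 1
                if counts[j] == 0:
                    nxt.append(j)
        fronts.append(sorted(nxt))
    return [f for f in fronts if f]


def crowding_distance(vectors: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance within one front; boundary points infinite."""
    n, m = vectors.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(vectors[:, k], kind="stable")
        vmin, vmax = vectors[order[0], k], vectors[order[-1], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        span = vmax - vmin
        if span == 0:
            continue
        for pos in range(1, n - 1):
            dist[order[pos]] += (vectors[order[pos + 1], k]
                                 - vectors[order[pos - 1], k]) / span
    return dist


def nsga2_select(population: list[Individual], k: int) -> list[Individual]:
    """Select exactly k survivors front-by-front, crowding on the split front.

    Ties in crowding distance break deterministically by position in the
    input population.
    """
    if k > len(population):
        raise ValueError("cannot select more individuals than the population holds")
    vectors = np.vstack([ind.minimization_vector() for ind in population])
    selected: list[int] = []
    for front in fast_non_dominated_sort(vectors):
        if len(selected) + len(front) <= k:
            selected.extend(front)
        else:
            cd = crowding_distance(vectors[front])
            ranked = sorted(range(len(front)), key=lambda i: (-cd[i], front[i]))
            selected.extend(front[i] for i in ranked[: k - len(selected)])
        if len(selected) == k:
            break
    return [population[i] for i in selected]


# ---------------------------------------------------------------------------
# GA driver


@dataclass
class HallOfFame:
    """Best-by-validation-Specificity and best-by-validation-Sensitivity masks.

    Mirrors picking one specificity-oriented model (good at clearing
    nontoxic compounds) and one sensitivity-oriented model (good at flagging
    toxic ones); MCC on validation breaks ties.
    """

    best_specificity: Individual | None = None
    best_sensitivity: Individual | None = None

    def update(self, individuals: Sequence[Individual]) -> None:
        for ind in individuals:
            if ind.val_report is None:
                continue
            if _better(ind, self.best_specificity, "spec"):
                self.best_specificity = ind.copy()
            if _better(ind, self.best_sensitivity, "sens"):
                self.best_sensitivity = ind.copy()


def _better(cand: Individual, incumbent: Individual | None, attr: str) -> bool:
    cv = getattr(cand.val_report, attr)
    if cv is None:
        return False
    if incumbent is None:
        return True
    iv = getattr(incumbent.val_report, attr)
    if iv is None or cv > iv:
        return True
    return cv == iv and cand.val_report.mcc > incumbent.val_report.mcc


def run_ga(
    modeling_set: DescriptorMatrix,
    config: GAConfig,
    space: SearchSpace | None = None,
) -> tuple[list[Individual], HallOfFame, pd.DataFrame]:
    """Evolve descriptor masks; return final population, hall of fame, log.

    Each generation: operators produce offspring; masks changed by an
    operator are re-tuned; parents and offspring are all (re)evaluated on the
    generation's fresh resample; NSGA-II reduces parents+offspring back to
    the population size. The generations log records |mask| and the five
    objectives per individual.
    """
    config.validate()
    if space is None:
        space = default_search_space()
    n_desc = len(modeling_set.descriptor_names)
    rng = np.random.default_rng(derive_seed(config.seed, "ga-run"))

    def evaluate_all(pop: list[Individual], gen_seed: int, generation: int) -> None:
        for i, ind in enumerate(pop):
            try:
                evaluate_individual(ind, modeling_set, gen_seed, space=space,
                                    bayes_iterations=config.bayes_iterations,
                                    cv_folds=config.cv_folds,
                                    train_fraction=config.train_fraction)
            except Exception as exc:
                raise RuntimeError(
                    f"evaluation failed at generation {generation}, individual {i}"
                ) from exc

    log_rows: list[dict] = []

    def log_generation(pop: list[Individual], generation: int) -> None:
        for i, ind in enumerate(pop):
            row = {"generation": generation, "individual": i, "n_selected": ind.n_selected}
            row.update(dict(zip(OBJECTIVE_NAMES, ind.objectives)))
            log_rows.append(row)

    population = init_population(n_desc, config)
    hof = HallOfFame()
    gen_seed = derive_seed(config.seed, "generation-0")
    evaluate_all(population, gen_seed, 0)
    hof.update(population)
    log_generation(population, 0)

    for g in range(1, config.n_generations + 1):
        op_rng = np.random.default_rng(derive_seed(config.seed, f"operators-{g}"))
        offspring = apply_operators(population, config, op_rng)
        gen_seed = derive_seed(config.seed, f"generation-{g}")
        evaluate_all(offspring, gen_seed, g)
        # Parents are re-scored on the same fresh resample (no re-tuning) so
        # the mu+lambda pool is comparable within the generation.
        for ind in population:
            evaluate_individual(ind, modeling_set, gen_seed, space=space,
                                bayes_iterations=config.bayes_iterations,
                                cv_folds=config.cv_folds,
                                train_fraction=config.train_fraction, retune=False)
        pool = population + offspring
        hof.update(pool)
        population = nsga2_select(pool, config.population_size)
        log_generation(population, g)
        log.info("generation %d: median |mask| %.1f, best MCC_val %.3f", g,
                 float(np.median([ind.n_selected for ind in population])),
                 max(ind.objectives[1] for ind in population))

    return population, hof, pd.DataFrame(log_rows)
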