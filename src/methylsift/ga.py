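"""Genetic-algorithm wrapper feature selection.

Each chromosome is a binary inclusion mask over the candidate CpG
universe, constrained to carry between 1 and D_max ones.  Fitness is
the pooled total accuracy of the distance-weighted 12-nn classifier on
a stratified three-fold cross-validation restricted to the masked
features; the fold assignment is fixed per run so every chromosome is
scored on identical folds.  Selection is fitness-proportional roulette,
crossover is uniform (pairs crossed with probability Pc = 0.5, each bit
swapped with probability 0.5), mutation flips bits independently with
probability Pm = 1/N, and a repair step restores the cardinality
bounds.  One elite chromosome survives unchanged per generation, so the
best fitness is non-decreasing and the winner of the final generation
is the global best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import knn_weighted_predict


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 500
    p_crossover: float = 0.5
    p_mutation: float | None = None  # default 1/N, resolved at run time
    d_max: int = 150
    max_generations: int = 50
    elitism: int = 1
    k: int = 12
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.p_crossover <= 1.0:
            raise ValueError("p_crossover must lie in [0, 1]")
        if self.p_mutation is not None and not 0.0 <= self.p_mutation <= 1.0:
            raise ValueError("p_mutation must lie in [0, 1]")
        if self.d_max < 1 or self.max_generations < 1 or self.cv_folds < 2:
            raise ValueError("invalid GA config")

    def pm(self, n_features: int) -> float:
        return 1.0 / n_features if self.p_mutation is None else self.p_mutation


@dataclass(frozen=True)
class GenerationLog:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_cardinality: int


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def init_population(cfg: GAConfig, n_features: int) -> list[np.ndarray]:
    """population_size boolean masks with cardinality uniform in [1, D_max]."""
    if cfg.d_max > n_features:
        raise ValueError("d_max exceeds the feature-universe size")
    rng = _rng(cfg.seed, 31)
    pop = []
    for _ in range(cfg.population_size):
        card = int(rng.integers(1, cfg.d_max + 1))
        mask = np.zeros(n_features, dtype=bool)
        mask[rng.choice(n_features, size=card, replace=False)] = True
        pop.append(mask)
    return pop


def make_cv_folds(labels, cv_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds fixed per run (mask-independent)."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < cv_folds:
        raise ValueError("each class needs at least cv_folds members")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**31))
    return list(skf.split(np.zeros(len(labels)), labels))


def knn_cv_fitness(mask, X, labels, cfg: GAConfig, folds=None) -> float:
    """Pooled accuracy of the k-nn weighted classifier over stratified
    cross-validation, restricted to the masked features."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("mask must include at least one feature")
    X = np.asarray(X, dtype=float)[:, mask]
    labels = np.asarray(labels)
    if folds is None:
        folds = make_cv_folds(labels, cfg.cv_folds, cfg.seed)
    correct = 0
    for train_idx, test_idx in folds:
        k = min(cfg.k, len(train_idx))
        pred = knn_weighted_predict(X[train_idx], labels[train_idx], X[test_idx], k)
        correct += int((pred == labels[test_idx]).sum())
    return correct / len(labels)


def roulette_select(population, fitnesses, n_draws: int, rng) -> list[np.ndarray]:
    """Fitness-proportional sampling with replacement; all-zero fitness
    falls back to uniform."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if (fitnesses < 0).any():
        raise ValueError("fitnesses must be non-negative")
    total = fitnesses.sum()
    p = np.full(len(population), 1.0 / len(population)) if total == 0 else fitnesses / total
    idx = rng.choice(len(population), size=n_draws, replace=True, p=p)
    return [population[i].copy() for i in idx]


def uniform_crossover(parent_a, parent_b, p_crossover: float, rng):
    """With probability p_crossover, swap each bit independently with
    probability 0.5; otherwise return copies of the parents."""
    if len(parent_a) != len(parent_b):
        raise ValueError("parent length mismatch")
    a, b = parent_a.copy(), parent_b.copy()
    if rng.random() < p_crossover:
        swap = rng.random(len(a)) < 0.5
        a[swap], b[swap] = parent_b[swap], parent_a[swap]
    return a, b


def bit_mutate(mask, p_mutation: float, rng) -> np.ndarray:
    """Flip each bit independently with probability p_mutation."""
    if not 0.0 <= p_mutation <= 1.0:
        raise ValueError("p_mutation must lie in [0, 1]")
    flips = rng.random(len(mask)) < p_mutation
    return mask ^ flips


def cardinality_repair(mask, d_max: int, rng) -> np.ndarray:
    """Clear random surplus ones above d_max; set one random bit if
    empty; leave in-range masks untouched."""
    mask = mask.copy()
    ones = np.flatnonzero(mask)
    if len(ones) > d_max:
        drop = rng.choice(ones, size=len(ones) - d_max, replace=False)
        mask[drop] = False
    elif len(ones) == 0:
        mask[int(rng.integers(len(mask)))] = True
    return mask


def _mask_key(mask: np.ndarray) -> bytes:
    return np.packbits(mask).tobytes()


def _better(fit_a, mask_a, fit_b, mask_b) -> bool:
    """True when (fit_a, mask_a) beats (fit_b, mask_b): higher fitness,
    then smaller cardinality, then lexicographically smaller mask."""
    if fit_a != fit_b:
        return fit_a > fit_b
    ca, cb = int(mask_a.sum()), int(mask_b.sum())
    if ca != cb:
        return ca < cb
    return _mask_key(mask_a) < _mask_key(mask_b)


def evolve(X, labels, cfg: GAConfig):
    """Run the full GA loop; returns (best mask, generation log list).

    Fitness evaluations are cached by mask, and the per-generation log
    records best/mean fitness and the best mask's cardinality.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n_features = X.shape[1]
    pm = cfg.pm(n_features)
    folds = make_cv_folds(labels, cfg.cv_folds, cfg.seed)
    rng = _rng(cfg.seed, 37)
    cache: dict[bytes, float] = {}

    def fitness(mask) -> float:
        key = _mask_key(mask)
        if key not in cache:
            cache[key] = knn_cv_fitness(mask, X, labels, cfg, folds=folds)
        return cache[key]

    population = init_population(cfg, n_features)
    log: list[GenerationLog] = []
    for gen in range(cfg.max_generations):
        fits = [fitness(m) for m in population]
        best_i = 0
        for i in range(1, len(population)):
            if _better(fits[i], population[i], fits[best_i], population[best_i]):
                best_i = i
        log.append(
            GenerationLog(
                generation=gen,
                best_fitness=fits[best_i],
                mean_fitness=float(np.mean(fits)),
                best_cardinality=int(population[best_i].sum()),
            )
        )
        if gen == cfg.max_generations - 1:
            return population[best_i].copy(), log

        elite = [population[best_i].copy() for _ in range(max(cfg.elitism, 0))]
        parents = roulette_select(population, fits, cfg.population_size, rng)
        children = []
        for j in range(0, len(parents) - 1, 2):
            a, b = uniform_crossover(parents[j], parents[j + 1], cfg.p_crossover, rng)
            children.extend((a, b))
        if len(parents) % 2:
            children.append(parents[-1].copy())
        children = [
            cardinality_repair(bit_mutate(c, pm, rng), cfg.d_max, rng) for c in children
        ]
        population = (elite + children)[: cfg.population_size]
    raise AssertionError("unreachable")
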