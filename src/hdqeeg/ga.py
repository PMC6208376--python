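"""Generic genetic algorithm over fixed-size feature subsets.

Chromosomes are sets of feature indices of fixed size.  Selection is by
tournament, crossover samples a child from the union of two parents
(duplicates repaired with random unused indices), mutation replaces
individual genes with random unused indices, and elitism carries the
best chromosomes over unchanged — so the best fitness per generation is
nondecreasing.  Fitness values are cached per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class GAConfig:
    subset_size: int = 20
    population: int = 100
    generations: int = 50
    tournament_size: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.05
    elitism: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.elitism >= self.population:
            raise ValueError("elitism must be < population")


def _random_subset(rng: np.random.Generator, n_features: int, size: int) -> tuple[int, ...]:
    return tuple(sorted(rng.choice(n_features, size=size, replace=False).tolist()))


def _crossover(rng, a: tuple, b: tuple, n_features: int, size: int) -> tuple[int, ...]:
    union = np.array(sorted(set(a) | set(b)))
    if len(union) >= size:
        child = set(rng.choice(union, size=size, replace=False).tolist())
    else:  # identical parents cannot fill the child; pad with unused indices
        child = set(union.tolist())
    while len(child) < size:
        child.add(int(rng.integers(n_features)))
    return tuple(sorted(child))


def _mutate(rng, chrom: tuple, n_features: int, rate: float) -> tuple[int, ...]:
    genes = set(chrom)
    for g in chrom:
        if rng.random() < rate:
            genes.discard(g)
            replacement = int(rng.integers(n_features))
            while replacement in genes:
                replacement = int(rng.integers(n_features))
            genes.add(replacement)
    return tuple(sorted(genes))


def ga_optimize(
    n_features: int,
    fitness: Callable[[tuple[int, ...]], float],
    config: GAConfig,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[int, ...], list[float]]:
    """Maximize ``fitness`` over index subsets of ``config.subset_size``.

    Returns the best-ever chromosome and the per-generation best-fitness
    trace (nondecreasing by elitism).
    """
    if config.subset_size > n_features:
        raise ValueError("subset_size exceeds number of features")
    rng = rng or np.random.default_rng(config.seed)
    cache: dict[tuple[int, ...], float] = {}

    def evaluate(chrom: tuple[int, ...]) -> float:
        if chrom not in cache:
            cache[chrom] = float(fitness(chrom))
        return cache[chrom]

    pop = [_random_subset(rng, n_features, config.subset_size) for _ in range(config.population)]
    fits = [evaluate(c) for c in pop]
    trace: list[float] = []
    for _ in range(config.generations):
        order = np.argsort(fits)[::-1]
        elite = [pop[i] for i in order[: config.elitism]]
        children = list(elite)
        while len(children) < config.population:
            idx = rng.integers(len(pop), size=config.tournament_size)
            p1 = pop[max(idx, key=lambda i: fits[i])]
            idx = rng.integers(len(pop), size=config.tournament_size)
            p2 = pop[max(idx, key=lambda i: fits[i])]
            if rng.random() < config.crossover_rate:
                child = _crossover(rng, p1, p2, n_features, config.subset_size)
            else:
                child = p1
            children.append(_mutate(rng, child, n_features, config.mutation_rate))
        pop = children
        fits = [evaluate(c) for c in pop]
        trace.append(max(fits))
    best = max(cache.items(), key=lambda kv: kv[1])[0]
    return best, trace
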