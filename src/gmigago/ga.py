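"""Generic elite-crossover genetic-algorithm loop.

Both search stages share the same scheme: keep a single elite
individual, cross every member of the current generation with it, mutate
the child, and let a strictly fitter child take over the elite slot
immediately. The loop stops at the generation budget or after the elite
fitness has stalled for ``patience`` consecutive generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

__all__ = ["GAConfig", "GAResult", "evolve"]


@dataclass
class GAConfig:
    population_size: int = 200
    generations: int = 20
    mutation_rate: float = 0.1
    patience: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class GAResult:
    elite: Any
    elite_fitness: float
    fitness_trace: list = field(default_factory=list)
    generations_run: int = 0
    terminated_by: str = "max_generations"
    n_evaluations: int = 0
    cache_hits: int = 0


def evolve(
    initial_population: Sequence,
    fitness: Callable[[Any], float],
    crossover: Callable,
    mutate: Callable,
    config: GAConfig,
    rng: np.random.Generator | None = None,
    key: Callable[[Any], Any] | None = None,
) -> GAResult:
    """Run the elite-crossover GA.

    Parameters
    ----------
    fitness : maps an individual to a finite real (larger is better).
    crossover : ``crossover(individual, elite, rng) -> child``.
    mutate : ``mutate(individual, mutation_rate, rng) -> individual``.
    key : optional canonical-hash function; when given, fitness values are
        memoized per canonical key (the fitness must be deterministic).

    The returned elite is the best individual ever evaluated: elite
    replacement is immediate (within the generation loop) and strict, so
    the per-generation fitness trace is monotone non-decreasing.
    """
    if not initial_population:
        raise ValueError("initial population must be non-empty")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    cache: dict[Any, float] = {}
    stats = {"evals": 0, "hits": 0}

    def evaluate(ind) -> float:
        if key is not None:
            k = key(ind)
            if k in cache:
                stats["hits"] += 1
                return cache[k]
        f = float(fitness(ind))
        if not np.isfinite(f):
            raise ValueError(f"fitness returned a non-finite value for individual {ind!r}")
        stats["evals"] += 1
        if key is not None:
            cache[k] = f
        return f

    population = list(initial_population)
    fits = [evaluate(ind) for ind in population]
    elite_idx = int(np.argmax(fits))
    elite, elite_fit = population[elite_idx], fits[elite_idx]

    trace: list[float] = []
    stall = 0
    terminated_by = "max_generations"
    generations_run = 0
    prev_fit = elite_fit
    for _ in range(config.generations):
        next_pop = []
        for ind in population:
            child = mutate(crossover(ind, elite, rng), config.mutation_rate, rng)
            f = evaluate(child)
            if f > elite_fit:
                elite, elite_fit = child, f
            next_pop.append(child)
        population = next_pop
        generations_run += 1
        trace.append(elite_fit)
        if elite_fit == prev_fit:
            stall += 1
        else:
            stall = 0
        prev_fit = elite_fit
        if stall >= config.patience:
            terminated_by = "stall"
            break
    return GAResult(
        elite=elite,
        elite_fitness=elite_fit,
        fitness_trace=trace,
        generations_run=generations_run,
        terminated_by=terminated_by,
        n_evaluations=stats["evals"],
        cache_hits=stats["hits"],
    )
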