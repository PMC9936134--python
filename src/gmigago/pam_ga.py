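"""Stage 1: GA-driven medoid search (PAM-GA).

Replaces PAM's blind random medoid updates with an elite-crossover GA
over medoid sets, scored by the mean silhouette under the 1 − Pearson
distance. The PAM solution is seeded into the initial population, so the
final silhouette can never fall below the PAM one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .distance import ClusterAssignment, DistanceMatrix, distance_matrix, mean_silhouette
from .expression import ExpressionMatrix
from .ga import GAConfig, GAResult, evolve
from .pam import KScanResult, MedoidSet, assign_to_medoids, pam_run, scan_k

__all__ = [
    "pamga_init_population",
    "pamga_crossover",
    "pamga_mutate",
    "run_pam_ga",
    "PAMGA",
]


def pamga_init_population(
    D: DistanceMatrix,
    k: int,
    P: int,
    pam_solution: MedoidSet,
    rng: np.random.Generator,
) -> list[MedoidSet]:
    """P − 1 uniform-random k-subsets of genes plus the PAM solution."""
    if P < 2:
        raise ValueError("population size must be >= 2")
    n = D.n
    population: list[MedoidSet] = [tuple(int(m) for m in pam_solution)]
    for _ in range(P - 1):
        population.append(tuple(int(i) for i in rng.choice(n, size=k, replace=False)))
    return population


def pamga_crossover(
    parent: MedoidSet, elite: MedoidSet, rng: np.random.Generator
) -> MedoidSet:
    """Merge both parents' elements, then draw k of them without replacement."""
    k = len(parent)
    union = sorted(set(parent) | set(elite))
    if len(union) == k:
        return tuple(union)
    return tuple(int(i) for i in rng.choice(union, size=k, replace=False))


def pamga_mutate(
    ind: MedoidSet, mu: float, n: int, rng: np.random.Generator
) -> MedoidSet:
    """With probability ``mu`` (per individual) swap one element for a
    uniformly chosen gene outside the set; duplicates are impossible by
    construction."""
    if rng.random() >= mu:
        return ind
    outside = np.setdiff1d(np.arange(n), ind)
    if outside.size == 0:
        return ind  # k == n: nothing to add, logged no-op
    drop = int(rng.integers(len(ind)))
    add = int(rng.choice(outside))
    child = list(ind)
    child[drop] = add
    return tuple(child)


@dataclass
class PamGaOutcome:
    medoids: MedoidSet
    assignment: ClusterAssignment
    silhouette: float
    ga: GAResult
    seed_silhouette: float


def run_pam_ga(
    D: DistanceMatrix,
    k: int,
    config: GAConfig,
    pam_solution: MedoidSet | None = None,
    b_mode: str = "nearest_other",
    pam_max_iter: int = 2000,
    rng: np.random.Generator | None = None,
) -> PamGaOutcome:
    """Evolve medoid sets with silhouette fitness; thin functional wrapper
    over what :class:`PAMGA` does after k is fixed."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if pam_solution is None:
        pam_solution = pam_run(D, k, max_iter=pam_max_iter, rng=rng).medoids
    seed_s = mean_silhouette(assign_to_medoids(D, pam_solution), D, b_mode=b_mode)

    def fitness(ind: MedoidSet) -> float:
        return mean_silhouette(assign_to_medoids(D, ind), D, b_mode=b_mode)

    def mutate(ind, mu, rng_):
        return pamga_mutate(ind, mu, D.n, rng_)

    population = pamga_init_population(D, k, config.population_size, pam_solution, rng)
    result = evolve(
        population,
        fitness,
        pamga_crossover,
        mutate,
        config,
        rng=rng,
        key=lambda ind: tuple(sorted(ind)),
    )
    elite = tuple(result.elite)
    assignment = assign_to_medoids(D, elite)
    return PamGaOutcome(elite, assignment, result.elite_fitness, result, seed_s)


class PAMGA(ClusterMixin, BaseEstimator):
    """Co-expression gene clustering by PAM seeding plus GA medoid search.

    Parameters
    ----------
    k : int or "scan"
        Cluster count. With ``"scan"``, plain PAM is run for every k in
        ``[k_min, k_max]`` and the k with the best mean silhouette wins
        (ties toward the smaller k); that k is then frozen for the GA.
    k_min, k_max : scan range (defaults 8–20).
    population_size, generations, mutation_rate, patience : GA settings.
        ``population_size`` defaults to 200 for library use; 8000 is the
        paper-scale setting for large datasets.
    pam_max_iter : random-swap proposals per PAM run.
    b_mode : "nearest_other" (standard silhouette) or "pooled_other"
        (b_i pooled over all genes outside the cluster).
    metric : "pearson" (compute 1 − r from expression rows) or
        "precomputed" (X is already a distance matrix).
    random_state : int seed; all randomness in fit derives from it.

    Attributes
    ----------
    k_ : chosen cluster count.
    medoids_ : tuple of medoid gene indices.
    labels_ : cluster label per gene.
    silhouette_ : mean silhouette of the final clustering.
    pam_silhouette_ : mean silhouette of the seeding PAM solution.
    fitness_trace_ : per-generation elite silhouette (non-decreasing).
    scan_table_ : list of (k, S) pairs when k was scanned, else None.
    """

    def __init__(
        self,
        k="scan",
        k_min: int = 8,
        k_max: int = 20,
        population_size: int = 200,
        generations: int = 20,
        mutation_rate: float = 0.1,
        patience: int = 3,
        pam_max_iter: int = 2000,
        b_mode: str = "nearest_other",
        metric: str = "pearson",
        random_state=None,
    ):
        self.k = k
        self.k_min = k_min
        self.k_max = k_max
        self.population_size = population_size
        self.generations = generations
        self.mutation_rate = mutation_rate
        self.patience = patience
        self.pam_max_iter = pam_max_iter
        self.b_mode = b_mode
        self.metric = metric
        self.random_state = random_state

    def _as_distance(self, X) -> DistanceMatrix:
        if isinstance(X, DistanceMatrix):
            return X
        if self.metric == "precomputed":
            X = np.asarray(X, dtype=float)
            return DistanceMatrix([str(i) for i in range(X.shape[0])], X)
        if isinstance(X, ExpressionMatrix):
            return distance_matrix(X)
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            return distance_matrix(ExpressionMatrix.from_dataframe(X))
        X = np.asarray(X, dtype=float)
        em = ExpressionMatrix(
            [str(i) for i in range(X.shape[0])],
            [str(j) for j in range(X.shape[1])],
            np.abs(X) if (X < 0).any() else X,
        )
        return distance_matrix(em)

    def fit(self, X, y=None):
        """Cluster genes (rows of X). X may be an ExpressionMatrix, a
        genes × samples DataFrame/array, or a precomputed distance matrix."""
        D = self._as_distance(X)
        rng = np.random.default_rng(self.random_state)
        self.scan_table_ = None
        if self.k == "scan":
            scan: KScanResult = scan_k(
                D,
                k_min=self.k_min,
                k_max=self.k_max,
                max_iter=self.pam_max_iter,
                rng=rng,
                b_mode=self.b_mode,
            )
            k = scan.k_star
            pam_solution = scan.best.medoids
            self.scan_table_ = scan.table
        else:
            k = int(self.k)
            pam_solution = pam_run(D, k, max_iter=self.pam_max_iter, rng=rng).medoids
        config = GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            mutation_rate=self.mutation_rate,
            patience=self.patience,
        )
        out = run_pam_ga(
            D, k, config, pam_solution=pam_solution, b_mode=self.b_mode, rng=rng
        )
        self.distance_ = D
        self.k_ = k
        self.medoids_ = out.medoids
        self.labels_ = out.assignment.labels
        self.assignment_ = out.assignment
        self.silhouette_ = out.silhouette
        self.pam_silhouette_ = out.seed_silhouette
        self.fitness_trace_ = out.ga.fitness_trace
        self.n_generations_ = out.ga.generations_run
        self.terminated_by_ = out.ga.terminated_by
        return self
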