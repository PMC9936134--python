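"""Stage 2: overlapping-module refinement by functional-similarity
optimization (FSO-GA).

The stage-1 partition is relaxed into a binary gene × module membership
matrix. Each gene may join any module whose medoid lies closer than a
box-plot outlier threshold (Q3 + 1.5·(Q3 − Q1) of that module's
member-to-medoid distances), which yields a per-gene list of potential
membership modules. A second elite-crossover GA then searches the
constrained space of membership matrices, maximizing

    Target = Sim · alpha + Sig

where Sim is the mean pairwise Lin similarity among each module's
significantly enriched biological-process terms and Sig aggregates the
−log10 adjusted p-values of those terms, normalized by the module count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .distance import ClusterAssignment, DistanceMatrix
from .enrichment import ModuleFunctionProfile, enrich_module
from .ga import GAConfig, GAResult, evolve
from .ontology import AnnotationCorpus, GoDag, lin_similarity
from .pam import MedoidSet

__all__ = [
    "FsoConfig",
    "PotentialModules",
    "membership_threshold",
    "build_potential_modules",
    "validate_membership",
    "partition_to_membership",
    "fsoga_init",
    "fsoga_crossover",
    "fsoga_mutate",
    "functional_scores",
    "FitnessEvaluator",
    "run_fso_ga",
    "FSOGA",
]


@dataclass
class FsoConfig:
    """FSO-GA settings. ``over`` (module overlap probability) and
    ``alpha`` (similarity weight in the fitness) have no universal
    defaults — they are dataset-dependent and must be set explicitly."""

    over: float
    alpha: float
    population_size: int = 1000
    generations: int = 20
    mutation_rate: float = 0.1
    patience: int = 3
    alpha_sig: float = 0.05
    top: int = 20
    sig_norm: str = "module_count"  # or "per_term"
    lin_mode: str = "mica"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.over <= 1:
            raise ValueError("over must be in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.sig_norm not in ("module_count", "per_term"):
            raise ValueError("sig_norm must be 'module_count' or 'per_term'")

    def ga_config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            mutation_rate=self.mutation_rate,
            patience=self.patience,
            seed=self.seed,
        )


def membership_threshold(cluster_distances: Sequence[float]) -> float:
    """Box-plot upper outlier cutoff Q3 + 1.5·(Q3 − Q1); quartiles by
    linear interpolation between order statistics."""
    d = np.asarray(list(cluster_distances), dtype=float)
    if d.size == 0:
        raise ValueError("need at least one distance")
    q1, q3 = np.percentile(d, [25, 75])
    return float(q3 + 1.5 * (q3 - q1))


@dataclass
class PotentialModules:
    """Per-gene ordered lists of candidate modules.

    ``lists[i]`` holds the module indices whose medoid is closer to gene
    i than that module's threshold, ordered by ascending distance; the
    gene's stage-1 module is always present. ``dist[i, j]`` is the
    distance from gene i to module j's medoid, used for deterministic
    repair of emptied modules.
    """

    lists: list[list[int]]
    dist: np.ndarray  # (n, k) gene-to-medoid distances
    thresholds: np.ndarray  # (k,)
    stage1_labels: np.ndarray

    @property
    def n(self) -> int:
        return len(self.lists)

    @property
    def k(self) -> int:
        return self.dist.shape[1]

    def M(self, i: int) -> int:
        return len(self.lists[i])


def build_potential_modules(
    D: DistanceMatrix, medoids: MedoidSet, assign: ClusterAssignment
) -> PotentialModules:
    """Candidate-module lists from the stage-1 clustering.

    Each module's threshold comes from its own members' distances to its
    medoid. Gene i's list contains every module j with
    ``dist(i, medoid_j) < threshold_j`` (strict) plus, always, its
    stage-1 module.
    """
    med = list(medoids)
    k = len(med)
    dist = D.D[:, med]  # (n, k)
    thresholds = np.empty(k)
    for j in range(k):
        members = assign.members(j)
        thresholds[j] = membership_threshold(dist[members, j])
    lists: list[list[int]] = []
    for i in range(D.n):
        candidates = set(np.flatnonzero(dist[i] < thresholds).tolist())
        candidates.add(int(assign.labels[i]))
        ordered = sorted(candidates, key=lambda j: (dist[i, j], j))
        lists.append([int(j) for j in ordered])
    return PotentialModules(lists, dist, thresholds, assign.labels.copy())


def partition_to_membership(assign: ClusterAssignment) -> np.ndarray:
    """Encode a hard partition as a binary membership matrix."""
    A = np.zeros((assign.n, assign.k), dtype=np.uint8)
    A[np.arange(assign.n), assign.labels] = 1
    return A


def validate_membership(A: np.ndarray, potential: PotentialModules) -> None:
    """Raise unless A is a legal membership matrix for these candidate lists."""
    A = np.asarray(A)
    if A.shape != (potential.n, potential.k):
        raise ValueError(f"membership shape {A.shape} != ({potential.n}, {potential.k})")
    if not np.isin(A, (0, 1)).all():
        raise ValueError("membership entries must be 0/1")
    for i in range(potential.n):
        row = np.flatnonzero(A[i])
        if len(row) == 0:
            raise ValueError(f"gene {i} belongs to no module")
        allowed = set(potential.lists[i])
        if not set(row.tolist()) <= allowed:
            raise ValueError(
                f"gene {i} assigned outside its potential modules: "
                f"{sorted(set(row.tolist()) - allowed)}"
            )
    empty = np.flatnonzero(A.sum(axis=0) == 0)
    if empty.size:
        raise ValueError(f"empty module columns: {empty.tolist()}")


def _repair_empty_columns(A: np.ndarray, potential: PotentialModules) -> np.ndarray:
    """Re-populate emptied modules with the closest gene listing them."""
    for j in np.flatnonzero(A.sum(axis=0) == 0):
        candidates = [i for i in range(potential.n) if j in potential.lists[i]]
        best = min(candidates, key=lambda i: (potential.dist[i, j], i))
        A[best, j] = 1
    return A


def _draw_row(
    i: int, potential: PotentialModules, over: float, rng: np.random.Generator
) -> list[int]:
    """Sample the modules of one gene per the initialization rule."""
    lst = potential.lists[i]
    M = len(lst)
    if M == 1:
        return [lst[0]]
    if over >= 1.0:
        count = int(rng.integers(1, M + 1))
    elif rng.random() < over:
        count = int(rng.integers(2, M + 1))
    else:
        count = 1
    chosen = rng.choice(len(lst), size=count, replace=False)
    return [lst[int(c)] for c in chosen]


def _random_individual(
    potential: PotentialModules, over: float, rng: np.random.Generator
) -> np.ndarray:
    A = np.zeros((potential.n, potential.k), dtype=np.uint8)
    for i in range(potential.n):
        for j in _draw_row(i, potential, over, rng):
            A[i, j] = 1
    return _repair_empty_columns(A, potential)


def fsoga_init(
    potential: PotentialModules,
    over: float,
    P: int,
    seed_matrix: np.ndarray,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """P individuals: the stage-1 partition plus P − 1 random draws."""
    if P < 1:
        raise ValueError("population size must be >= 1")
    population = [np.asarray(seed_matrix, dtype=np.uint8).copy()]
    for _ in range(P - 1):
        population.append(_random_individual(potential, over, rng))
    return population


def fsoga_crossover(
    A1: np.ndarray,
    A2: np.ndarray,
    rng: np.random.Generator,
    potential: PotentialModules,
) -> np.ndarray:
    """Single-point row crossover: rows 1..cut from one parent, the rest
    from the other; emptied modules are repaired deterministically."""
    n = A1.shape[0]
    cut = int(rng.integers(1, n + 1))
    child = np.vstack([A1[:cut], A2[cut:]]).astype(np.uint8)
    return _repair_empty_columns(child, potential)


def fsoga_mutate(
    A: np.ndarray,
    mu: float,
    potential: PotentialModules,
    over: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independently redraw each gene's row with probability ``mu``."""
    A = A.copy()
    for i in range(potential.n):
        if rng.random() < mu:
            A[i, :] = 0
            for j in _draw_row(i, potential, over, rng):
                A[i, j] = 1
    return _repair_empty_columns(A, potential)


def functional_scores(
    module_terms: Sequence[Sequence[tuple[str, float]]],
    lin_fn: Callable[[str, str], float],
    n_modules: int,
    sig_norm: str = "module_count",
) -> tuple[float, float]:
    """Compute (Sim, Sig) from per-module retained enriched terms.

    ``module_terms[m]`` lists ``(term, p_adj)`` pairs retained for module
    m. Within a module holding num ≥ 2 terms, each term's Sim_i is the
    mean Lin similarity to the module's other terms; Sim averages Sim_i
    over all such terms. Modules with a single retained term contribute
    to Sig only. Sig sums −log10 p_adj over every retained term and
    divides by the module count (or by the term count with
    ``sig_norm="per_term"``).
    """
    sim_terms: list[float] = []
    neglog_sum = 0.0
    total_terms = 0
    for terms in module_terms:
        terms = list(terms)
        total_terms += len(terms)
        for _, p_adj in terms:
            neglog_sum += -math.log10(p_adj)
        num = len(terms)
        if num >= 2:
            for i in range(num):
                others = [lin_fn(terms[i][0], terms[j][0]) for j in range(num) if j != i]
                sim_terms.append(sum(others) / (num - 1))
    sim = float(np.mean(sim_terms)) if sim_terms else 0.0
    if sig_norm == "module_count":
        sig = neglog_sum / n_modules if n_modules else 0.0
    else:
        sig = neglog_sum / total_terms if total_terms else 0.0
    return sim, sig


@dataclass
class FitnessBreakdown:
    target: float
    sim: float
    sig: float


class FitnessEvaluator:
    """Target = Sim·alpha + Sig over a membership matrix, with per-module
    enrichment profiles and pairwise Lin values memoized (enrichment is
    the cost bottleneck, and module gene-sets recur heavily across
    individuals under elite crossover)."""

    def __init__(
        self,
        gene_ids: Sequence[str],
        dag: GoDag,
        corpus: AnnotationCorpus,
        config: FsoConfig,
    ):
        self.gene_ids = [str(g) for g in gene_ids]
        self.dag = dag
        self.corpus = corpus
        self.config = config
        self._profile_cache: dict[frozenset, ModuleFunctionProfile] = {}
        self._lin_cache: dict[frozenset, float] = {}

    def _lin(self, t1: str, t2: str) -> float:
        key = frozenset((t1, t2))
        val = self._lin_cache.get(key)
        if val is None:
            val = lin_similarity(t1, t2, self.dag, self.corpus, mode=self.config.lin_mode)
            self._lin_cache[key] = val
        return val

    def _profile(self, gene_set: frozenset, module_id: int) -> ModuleFunctionProfile:
        prof = self._profile_cache.get(gene_set)
        if prof is None:
            prof = enrich_module(
                gene_set,
                self.dag,
                self.corpus,
                alpha_sig=self.config.alpha_sig,
                top=self.config.top,
            )
            self._profile_cache[gene_set] = prof
        return prof

    def profiles(self, A: np.ndarray) -> list[ModuleFunctionProfile]:
        out = []
        for j in range(A.shape[1]):
            genes = frozenset(self.gene_ids[i] for i in np.flatnonzero(A[:, j]))
            out.append(self._profile(genes, j))
        return out

    def breakdown(self, A: np.ndarray) -> FitnessBreakdown:
        profs = self.profiles(A)
        module_terms = [[(r.term, r.p_adj) for r in p.rows] for p in profs]
        sim, sig = functional_scores(
            module_terms, self._lin, n_modules=A.shape[1], sig_norm=self.config.sig_norm
        )
        return FitnessBreakdown(sim * self.config.alpha + sig, sim, sig)

    def __call__(self, A: np.ndarray) -> float:
        return self.breakdown(A).target


@dataclass
class FsoGaOutcome:
    membership: np.ndarray
    target: float
    sim: float
    sig: float
    seed_target: float
    seed_sim: float
    seed_sig: float
    ga: GAResult
    potential: PotentialModules


def run_fso_ga(
    stage1: tuple[MedoidSet, ClusterAssignment],
    D: DistanceMatrix,
    dag: GoDag,
    corpus: AnnotationCorpus,
    config: FsoConfig,
    rng: np.random.Generator | None = None,
) -> FsoGaOutcome:
    """Evolve overlapping membership matrices from a stage-1 clustering;
    thin functional wrapper over what :class:`FSOGA` does in fit."""
    medoids, assign = stage1
    rng = np.random.default_rng(config.seed) if rng is None else rng
    potential = build_potential_modules(D, medoids, assign)
    seed_matrix = partition_to_membership(assign)
    evaluator = FitnessEvaluator(D.gene_ids, dag, corpus, config)
    seed_breakdown = evaluator.breakdown(seed_matrix)

    def crossover(A, elite, rng_):
        return fsoga_crossover(A, elite, rng_, potential)

    def mutate(A, mu, rng_):
        return fsoga_mutate(A, mu, potential, config.over, rng_)

    population = fsoga_init(potential, config.over, config.population_size, seed_matrix, rng)
    result = evolve(
        population,
        evaluator,
        crossover,
        mutate,
        config.ga_config(),
        rng=rng,
        key=lambda A: A.tobytes(),
    )
    elite = np.asarray(result.elite, dtype=np.uint8)
    b = evaluator.breakdown(elite)
    return FsoGaOutcome(
        membership=elite,
        target=b.target,
        sim=b.sim,
        sig=b.sig,
        seed_target=seed_breakdown.target,
        seed_sim=seed_breakdown.sim,
        seed_sig=seed_breakdown.sig,
        ga=result,
        potential=potential,
    )


class FSOGA(BaseEstimator):
    """Overlapping-module refinement of a gene clustering by GO-driven
    functional-similarity optimization.

    Parameters mirror :class:`FsoConfig`; ``dag`` and ``corpus`` supply
    the ontology and the gene → GO annotations. ``over`` and ``alpha``
    are dataset-dependent and required.

    Attributes
    ----------
    membership_ : binary (n_genes, k) matrix; overlapping allowed.
    sim_, sig_, target_ : scores of the elite matrix.
    seed_sim_, seed_sig_, seed_target_ : scores of the stage-1 partition.
    fitness_trace_ : per-generation elite Target (non-decreasing).
    potential_ : the per-gene candidate-module lists used as constraints.
    """

    def __init__(
        self,
        dag: GoDag,
        corpus: AnnotationCorpus,
        over: float,
        alpha: float,
        population_size: int = 1000,
        generations: int = 20,
        mutation_rate: float = 0.1,
        patience: int = 3,
        alpha_sig: float = 0.05,
        top: int = 20,
        sig_norm: str = "module_count",
        lin_mode: str = "mica",
        random_state=None,
    ):
        self.dag = dag
        self.corpus = corpus
        self.over = over
        self.alpha = alpha
        self.population_size = population_size
        self.generations = generations
        self.mutation_rate = mutation_rate
        self.patience = patience
        self.alpha_sig = alpha_sig
        self.top = top
        self.sig_norm = sig_norm
        self.lin_mode = lin_mode
        self.random_state = random_state

    def _config(self) -> FsoConfig:
        return FsoConfig(
            over=self.over,
            alpha=self.alpha,
            population_size=self.population_size,
            generations=self.generations,
            mutation_rate=self.mutation_rate,
            patience=self.patience,
            alpha_sig=self.alpha_sig,
            top=self.top,
            sig_norm=self.sig_norm,
            lin_mode=self.lin_mode,
        )

    def fit(self, D: DistanceMatrix, medoids: MedoidSet = None, labels=None):
        """Refine a stage-1 clustering given its distance matrix, medoid
        set, and hard labels (e.g. from a fitted :class:`PAMGA`)."""
        if medoids is None or labels is None:
            raise ValueError("fit requires the stage-1 medoids and labels")
        assign = labels if isinstance(labels, ClusterAssignment) else ClusterAssignment(
            np.asarray(labels), k=len(medoids)
        )
        rng = np.random.default_rng(self.random_state)
        out = run_fso_ga((tuple(medoids), assign), D, self.dag, self.corpus,
                         self._config(), rng=rng)
        self.membership_ = out.membership
        self.target_ = out.target
        self.sim_ = out.sim
        self.sig_ = out.sig
        self.seed_target_ = out.seed_target
        self.seed_sim_ = out.seed_sim
        self.seed_sig_ = out.seed_sig
        self.fitness_trace_ = out.ga.fitness_trace
        self.n_generations_ = out.ga.generations_run
        self.terminated_by_ = out.ga.terminated_by
        self.potential_ = out.potential
        self.gene_ids_ = list(D.gene_ids)
        return self

    def transform(self, D=None):
        """Return the fitted binary membership matrix."""
        return self.membership_
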