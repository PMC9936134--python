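"""Partitioning Around Medoids with a precomputed gene distance.

Classic PAM here means: k-means++-style seeding on the distance matrix,
then repeated random single-medoid swaps accepted only when they strictly
reduce the total within-cluster distance ``d_sum``. The cluster count k is
chosen by scanning a range and keeping the k with the best mean
silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import ClusterAssignment, DistanceMatrix, mean_silhouette

__all__ = [
    "MedoidSet",
    "PAMResult",
    "KScanResult",
    "kmeanspp_seed",
    "assign_to_medoids",
    "pam_run",
    "scan_k",
]

# A medoid set is an ordered tuple of k distinct gene indices; ties in
# gene-to-medoid assignment break toward the earliest position.
MedoidSet = tuple


def _validate_medoids(medoids, n: int) -> tuple:
    medoids = tuple(int(m) for m in medoids)
    if len(set(medoids)) != len(medoids):
        raise ValueError(f"duplicate medoid indices: {medoids}")
    if any(m < 0 or m >= n for m in medoids):
        raise ValueError(f"medoid index out of range [0, {n}): {medoids}")
    return medoids


def kmeanspp_seed(D: DistanceMatrix, k: int, rng: np.random.Generator) -> MedoidSet:
    """Dispersed initial medoids: first uniform, then ∝ squared distance
    to the nearest already-chosen medoid."""
    n = D.n
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= n (= {n}), got {k}")
    d = D.D
    first = int(rng.integers(n))
    medoids = [first]
    closest_sq = d[first] ** 2
    for _ in range(k - 1):
        weights = closest_sq.copy()
        weights[medoids] = 0.0
        total = weights.sum()
        if total == 0:
            # all remaining genes coincide with a chosen medoid; pick uniformly
            candidates = np.setdiff1d(np.arange(n), medoids)
            nxt = int(rng.choice(candidates))
        else:
            nxt = int(rng.choice(n, p=weights / total))
        medoids.append(nxt)
        closest_sq = np.minimum(closest_sq, d[nxt] ** 2)
    return tuple(medoids)


def assign_to_medoids(D: DistanceMatrix, M: MedoidSet) -> ClusterAssignment:
    """Nearest-medoid assignment; ties go to the earliest medoid position."""
    medoids = _validate_medoids(M, D.n)
    sub = D.D[:, list(medoids)]  # (n, k)
    labels = np.argmin(sub, axis=1)  # argmin takes the first minimum: tie rule
    # a medoid always owns its cluster, even when tied at distance 0 with
    # an earlier medoid (keeps every cluster non-empty)
    labels[list(medoids)] = np.arange(len(medoids))
    return ClusterAssignment(labels, k=len(medoids))


def _d_sum(D: DistanceMatrix, medoids: tuple, labels: np.ndarray) -> float:
    med = np.asarray(medoids)
    return float(D.D[np.arange(D.n), med[labels]].sum())


@dataclass
class PAMResult:
    medoids: MedoidSet
    assignment: ClusterAssignment
    d_sum: float
    d_sum_trace: list = field(default_factory=list)


def pam_run(
    D: DistanceMatrix,
    k: int,
    max_iter: int = 2000,
    rng: np.random.Generator | None = None,
    seed_medoids: MedoidSet | None = None,
) -> PAMResult:
    """Random-swap PAM: propose one medoid ↔ non-medoid swap per iteration
    and accept iff it strictly reduces ``d_sum``.

    The recorded ``d_sum_trace`` holds the incumbent value after each
    accepted or rejected proposal and is non-increasing by construction.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = D.n
    if seed_medoids is None:
        medoids = list(kmeanspp_seed(D, k, rng))
    else:
        medoids = list(_validate_medoids(seed_medoids, n))
        if len(medoids) != k:
            raise ValueError("seed_medoids size must equal k")
    assign = assign_to_medoids(D, tuple(medoids))
    best = _d_sum(D, tuple(medoids), assign.labels)
    trace = [best]
    in_set = np.zeros(n, dtype=bool)
    in_set[medoids] = True
    for _ in range(max_iter):
        pos = int(rng.integers(k))
        candidates = np.flatnonzero(~in_set)
        if candidates.size == 0:
            trace.append(best)
            continue
        repl = int(rng.choice(candidates))
        proposal = list(medoids)
        proposal[pos] = repl
        prop_assign = assign_to_medoids(D, tuple(proposal))
        prop_sum = _d_sum(D, tuple(proposal), prop_assign.labels)
        if prop_sum < best:
            in_set[medoids[pos]] = False
            in_set[repl] = True
            medoids = proposal
            best = prop_sum
        trace.append(best)
    final = tuple(medoids)
    return PAMResult(final, assign_to_medoids(D, final), best, trace)


@dataclass
class KScanResult:
    k_star: int
    best: PAMResult
    silhouette: float
    table: list  # (k, S) per scanned k


def scan_k(
    D: DistanceMatrix,
    k_min: int = 8,
    k_max: int = 20,
    max_iter: int = 2000,
    rng: np.random.Generator | None = None,
    b_mode: str = "nearest_other",
) -> KScanResult:
    """Run PAM for each k in [k_min, k_max] and keep the k with the highest
    mean silhouette; ties break toward the smaller k."""
    if k_min > k_max:
        raise ValueError("k_min must be <= k_max")
    if k_max > D.n:
        raise ValueError(f"k_max (= {k_max}) exceeds the gene count (= {D.n})")
    rng = np.random.default_rng() if rng is None else rng
    table = []
    best_k = None
    best_res = None
    best_s = -np.inf
    for k in range(k_min, k_max + 1):
        res = pam_run(D, k, max_iter=max_iter, rng=rng)
        s = mean_silhouette(res.assignment, D, b_mode=b_mode)
        table.append((k, s))
        if s > best_s:  # strict: ties keep the earlier (smaller) k
            best_k, best_res, best_s = k, res, s
    return KScanResult(best_k, best_res, best_s, table)
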