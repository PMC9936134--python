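"""Pearson-correlation gene distance and silhouette scoring.

The gene–gene distance is ``1 − r`` with ``r`` the sample Pearson
correlation of the two expression profiles, so perfectly co-expressed
genes sit at distance 0 and perfectly anti-correlated genes at 2. The
silhouette score computed on this distance is the fitness of the
stage-1 clustering search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression import ExpressionMatrix

__all__ = [
    "DistanceMatrix",
    "ClusterAssignment",
    "pearson_distance",
    "distance_matrix",
    "silhouette_gene",
    "silhouette_samples",
    "mean_silhouette",
]

B_MODES = ("nearest_other", "pooled_other")


@dataclass
class DistanceMatrix:
    """Symmetric n × n matrix of ``1 − Pearson r`` between gene profiles."""

    gene_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.gene_ids)
        if self.D.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.D.shape} != ({n}, {n})")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have a zero diagonal")
        if self.D.min() < -1e-9 or self.D.max() > 2 + 1e-9:
            raise ValueError("distances must lie in [0, 2]")

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.D, index=self.gene_ids, columns=self.gene_ids)


@dataclass
class ClusterAssignment:
    """A hard partition of genes into k clusters (stage-1 output)."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D array")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.labels.min(initial=0) < 0 or (len(self.labels) and self.labels.max() >= self.k):
            raise ValueError("labels must lie in [0, k)")
        used = np.unique(self.labels)
        if len(self.labels) and len(used) != self.k:
            missing = sorted(set(range(self.k)) - set(used.tolist()))
            raise ValueError(f"empty cluster indices: {missing}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def members(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.labels == j)


def pearson_distance(g1, g2) -> float:
    """``1 − Pearson r`` between two expression vectors; range [0, 2]."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1 or g1.size < 2:
        raise ValueError("expression vectors must be 1-D, equal length, and length >= 2")
    for name, v in (("first", g1), ("second", g2)):
        if np.ptp(v) == 0:
            raise ValueError(
                f"{name} vector is constant; drop constant genes during preprocessing"
            )
    a = g1 - g1.mean()
    b = g2 - g2.mean()
    denom = float(np.sqrt(a @ a) * np.sqrt(b @ b))
    if denom == 0:  # variance underflow: effectively constant
        raise ValueError(
            "vector variance underflows to zero; drop (near-)constant genes "
            "during preprocessing"
        )
    r = float(a @ b / denom)
    return float(np.clip(1.0 - r, 0.0, 2.0))


def distance_matrix(X: ExpressionMatrix) -> DistanceMatrix:
    """All-pairs ``1 − Pearson r`` over the rows of an expression matrix."""
    values = X.values
    stds = values.std(axis=1)
    if (stds == 0).any():
        bad = [g for g, s in zip(X.gene_ids, stds) if s == 0]
        raise ValueError(f"constant expression rows (zero variance): {bad}")
    corr = np.corrcoef(values)
    D = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return DistanceMatrix(list(X.gene_ids), D)


def _check_b_mode(b_mode: str) -> None:
    if b_mode not in B_MODES:
        raise ValueError(f"b_mode must be one of {B_MODES}, got {b_mode!r}")


def silhouette_samples(
    assign: ClusterAssignment, D: DistanceMatrix, b_mode: str = "nearest_other"
) -> np.ndarray:
    """Per-gene silhouette values s_i = (b_i − a_i) / max(a_i, b_i).

    a_i is the mean distance from gene i to the other members of its own
    cluster. b_i is, under ``nearest_other``, the smallest mean distance to
    any single other cluster (the standard definition); under
    ``pooled_other`` it is the mean distance to all genes outside i's
    cluster. Genes in singleton clusters get s_i = 0 by convention.
    """
    _check_b_mode(b_mode)
    labels = assign.labels
    n = assign.n
    if D.n != n:
        raise ValueError("assignment and distance matrix disagree on gene count")
    if assign.k < 2:
        raise ValueError("silhouette requires k >= 2")
    d = D.D
    sizes = np.bincount(labels, minlength=assign.k)
    # row sums of distance to each cluster, shape (n, k)
    cluster_sums = np.zeros((n, assign.k))
    for j in range(assign.k):
        cluster_sums[:, j] = d[:, labels == j].sum(axis=1)

    s = np.zeros(n)
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            s[i] = 0.0  # singleton convention
            continue
        a_i = cluster_sums[i, c] / (sizes[c] - 1)
        if b_mode == "nearest_other":
            others = [j for j in range(assign.k) if j != c]
            b_i = min(cluster_sums[i, j] / sizes[j] for j in others)
        else:
            n_out = n - sizes[c]
            b_i = (cluster_sums[i].sum() - cluster_sums[i, c]) / n_out
        denom = max(a_i, b_i)
        s[i] = 0.0 if denom == 0 else (b_i - a_i) / denom
    return s


def silhouette_gene(
    i: int, assign: ClusterAssignment, D: DistanceMatrix, b_mode: str = "nearest_other"
) -> float:
    """Silhouette value of a single gene."""
    return float(silhouette_samples(assign, D, b_mode=b_mode)[i])


def mean_silhouette(
    assign: ClusterAssignment, D: DistanceMatrix, b_mode: str = "nearest_other"
) -> float:
    """Arithmetic mean of the per-gene silhouette values (the stage-1 fitness)."""
    return float(silhouette_samples(assign, D, b_mode=b_mode).mean())
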