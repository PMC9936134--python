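"""GO over-representation analysis for gene modules.

One-sided hypergeometric tests against the annotated-gene universe of
the analyzed dataset, Benjamini–Hochberg adjustment across the module's
tested terms, then significance filtering and truncation to the top
terms by adjusted p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ontology import AnnotationCorpus, GoDag

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRow",
    "ModuleFunctionProfile",
    "hypergeom_test",
    "bh_adjust",
    "enrich_module",
]

_P_FLOOR = 1e-300  # guard against log10(0) on underflowed p-values


@dataclass
class EnrichmentRow:
    term: str
    overlap: int
    module_size: int
    term_size: int
    background_size: int
    p: float
    p_adj: float

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= min(self.module_size, self.term_size):
            raise ValueError("overlap must lie in [0, min(module_size, term_size)]")
        if not 0 < self.p <= 1 or self.p_adj < self.p - 1e-15:
            raise ValueError("require 0 < p <= 1 and p_adj >= p")


@dataclass
class ModuleFunctionProfile:
    """At most ``top`` significant enriched terms of one module, sorted by
    ascending adjusted p (ties by term ID)."""

    rows: list[EnrichmentRow] = field(default_factory=list)
    module_id: int | None = None

    @property
    def terms(self) -> list[str]:
        return [r.term for r in self.rows]

    @property
    def p_adj(self) -> list[float]:
        return [r.p_adj for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows)


def hypergeom_test(
    overlap: int, module_size: int, term_size: int, background_size: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap) of drawing
    ``overlap`` term-annotated genes in a module-sized draw."""
    if not (
        0 <= overlap <= module_size <= background_size
        and 0 <= term_size <= background_size
        and overlap <= term_size
    ):
        raise ValueError(
            "inconsistent counts: need overlap <= module_size <= background and "
            f"overlap <= term_size <= background, got {overlap=}, {module_size=}, "
            f"{term_size=}, {background_size=}"
        )
    return float(stats.hypergeom.sf(overlap - 1, background_size, term_size, module_size))


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_module(
    module_genes: Iterable[str],
    dag: GoDag,
    corpus: AnnotationCorpus,
    alpha_sig: float = 0.05,
    top: int = 20,
    module_id: int | None = None,
) -> ModuleFunctionProfile:
    """Over-representation profile of one gene module.

    Every term annotated (after ancestor propagation) to at least one
    module gene is tested against the corpus' annotated-gene universe;
    BH adjustment runs across all tested terms of this module; terms with
    adjusted p below ``alpha_sig`` are kept, truncated to the ``top``
    smallest (ties broken by term ID). Genes without annotations are
    dropped from the test universe.
    """
    module = set(module_genes) & corpus.genes
    if not module:
        logger.debug("module %s has no annotated genes; empty profile", module_id)
        return ModuleFunctionProfile(module_id=module_id)
    background = corpus.total_genes
    m = len(module)

    tested: list[tuple[str, int, int, float]] = []
    for term, genes in corpus.term_genes.items():
        overlap = len(module & genes)
        if overlap == 0:
            continue
        p = max(hypergeom_test(overlap, m, len(genes), background), _P_FLOOR)
        tested.append((term, overlap, len(genes), p))
    if not tested:
        return ModuleFunctionProfile(module_id=module_id)

    adj = bh_adjust([t[3] for t in tested])
    rows = [
        EnrichmentRow(term, overlap, m, size, background, p, max(float(pa), _P_FLOOR))
        for (term, overlap, size, p), pa in zip(tested, adj)
        if pa < alpha_sig
    ]
    rows.sort(key=lambda r: (r.p_adj, r.term))
    return ModuleFunctionProfile(rows=rows[:top], module_id=module_id)
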