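"""Gene Ontology handling: DAG, annotation corpus, information content,
and Lin term-to-term similarity.

Only the biological-process namespace is scored by default. Term
probabilities are annotation-frequency based: p(t) is the fraction of
annotated genes assigned (directly or through a descendant) to t, so the
namespace root has p = 1 and IC = −log p(t) grows toward the leaves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GoDag",
    "AnnotationCorpus",
    "load_obo",
    "read_annotation_table",
    "read_gaf",
    "merge_annotations",
    "lin_similarity",
]


@dataclass
class GoDag:
    """GO term graph restricted to one namespace, is_a edges by default.

    ``parents`` maps each term to its direct parents; a term's ancestor
    set always includes the term itself.
    """

    parents: dict[str, frozenset[str]]
    namespace: str = "biological_process"
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise ValueError(f"unknown parent term {p!r} (child {child!r})")
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"cycle in ontology is_a graph: {cycle}")
        self._graph = g

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    @property
    def roots(self) -> set[str]:
        return {t for t, ps in self.parents.items() if not ps}

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` through is_a links, term included."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        if term not in self.parents:
            raise KeyError(f"unknown term: {term!r}")
        result = {term}
        for p in self.parents[term]:
            result |= self.ancestors(p)
        out = frozenset(result)
        self._ancestors[term] = out
        return out


def load_obo(
    path,
    namespace: str | None = "biological_process",
    include_part_of: bool = False,
) -> GoDag:
    """Parse an OBO 1.2 ontology into a :class:`GoDag`.

    Obsolete terms are skipped. Terms are filtered to ``namespace`` when
    they declare one (pass ``namespace=None`` to keep everything). Only
    is_a edges are kept unless ``include_part_of`` is set.
    """
    graph = obonet.read_obo(path)  # skips obsolete stanzas
    undeclared = [t for t, data in graph.nodes(data=True) if not data]
    if undeclared:
        raise ValueError(f"edges reference undeclared terms: {sorted(undeclared)}")

    def in_namespace(data: dict) -> bool:
        if namespace is None:
            return True
        ns = data.get("namespace")
        return ns is None or ns == namespace

    keep = {t for t, data in graph.nodes(data=True) if in_namespace(data)}
    relations = {"is_a"} | ({"part_of"} if include_part_of else set())
    parents: dict[str, set[str]] = {t: set() for t in keep}
    for child, parent, rel in graph.edges(keys=True):
        if rel in relations and child in keep and parent in keep:
            parents[child].add(parent)
    return GoDag(
        {t: frozenset(ps) for t, ps in parents.items()},
        namespace=namespace or "any",
    )


@dataclass
class AnnotationCorpus:
    """Gene → GO-term assignments with ancestor-propagated term counts."""

    gene2terms: dict[str, frozenset[str]]  # direct annotations
    term_genes: dict[str, frozenset[str]]  # propagated gene sets per term
    total_genes: int

    @property
    def genes(self) -> set[str]:
        return set(self.gene2terms)

    def term_count(self, term: str) -> int:
        return len(self.term_genes.get(term, ()))

    def p(self, term: str) -> float:
        c = self.term_count(term)
        if c == 0:
            raise KeyError(f"term {term!r} has no annotated genes in the corpus")
        return c / self.total_genes

    def ic(self, term: str) -> float:
        """Information content −log p(t) (natural log)."""
        return -math.log(self.p(term))


def read_annotation_table(path) -> pd.DataFrame:
    """Two-column (gene, GO term) table, tab or comma delimited, no header
    required (a header row is detected by a 'GO:' prefix check)."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("annotation table must have two columns: gene, term")
    df = df.iloc[:, :2]
    df.columns = ["gene", "term"]
    # drop a header row if the term column clearly isn't a term ID
    if len(df) and not str(df.iloc[0, 1]).upper().startswith("GO:"):
        first_terms = df["term"].str.upper().str.startswith("GO:")
        if first_terms.iloc[1:].all() and not first_terms.iloc[0]:
            df = df.iloc[1:]
    return df.reset_index(drop=True)


def read_gaf(path, aspect: str | None = "P") -> pd.DataFrame:
    """Read a GAF 2.x file into a (gene, term) table.

    Uses column 2 (DB object symbol) and column 5 (GO ID); rows are
    filtered to the given aspect (column 9; "P" = biological process).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            if aspect is not None and parts[8] != aspect:
                continue
            rows.append((parts[1], parts[4]))
    return pd.DataFrame(rows, columns=["gene", "term"])


def merge_annotations(
    tables: Sequence[pd.DataFrame | str],
    dag: GoDag,
) -> AnnotationCorpus:
    """Union several (gene, term) tables into one corpus.

    Duplicate pairs collapse; terms absent from the DAG are dropped with a
    warning. Term counts are computed after propagating every gene's
    annotations to all is_a ancestors.
    """
    pairs: set[tuple[str, str]] = set()
    for table in tables:
        df = read_annotation_table(table) if not isinstance(table, pd.DataFrame) else table
        for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
            pairs.add((str(gene), str(term)))
    known = {(g, t) for g, t in pairs if t in dag}
    dropped = {t for _, t in pairs - known}
    if dropped:
        logger.warning("dropping %d annotation terms absent from the DAG: %s",
                       len(dropped), sorted(dropped)[:10])
    if not known:
        raise ValueError("no usable annotations after merging (empty corpus)")

    gene2terms: dict[str, set[str]] = {}
    for gene, term in known:
        gene2terms.setdefault(gene, set()).add(term)

    term_genes: dict[str, set[str]] = {}
    for gene, terms in gene2terms.items():
        closure: set[str] = set()
        for t in terms:
            closure |= dag.ancestors(t)
        for t in closure:
            term_genes.setdefault(t, set()).add(gene)
    return AnnotationCorpus(
        gene2terms={g: frozenset(ts) for g, ts in gene2terms.items()},
        term_genes={t: frozenset(gs) for t, gs in term_genes.items()},
        total_genes=len(gene2terms),
    )


def lin_similarity(
    t1: str,
    t2: str,
    dag: GoDag,
    corpus: AnnotationCorpus,
    mode: str = "mica",
) -> float:
    """Lin similarity of two GO terms, in [0, 1].

    The default picks the most informative common ancestor (MICA, the
    shared ancestor with the smallest p) and returns
    ``2·log p(MICA) / (log p(t1) + log p(t2))``. ``mode="literal"``
    instead takes the ancestor with the *largest* log p (the least
    informative one), kept only for auditability — it collapses most
    similarities to 0 because the namespace root (p = 1) is always a
    shared ancestor.
    """
    if mode not in ("mica", "literal"):
        raise ValueError(f"mode must be 'mica' or 'literal', got {mode!r}")
    for t in (t1, t2):
        if corpus.term_count(t) == 0:
            raise KeyError(f"term {t!r} absent from the annotation corpus")
    common = dag.ancestors(t1) & dag.ancestors(t2)
    common = {t for t in common if corpus.term_count(t) > 0}
    if not common:
        return 0.0
    logs = [math.log(corpus.p(t)) for t in common]
    log_anc = min(logs) if mode == "mica" else max(logs)
    denom = math.log(corpus.p(t1)) + math.log(corpus.p(t2))
    if denom == 0:  # both terms are the root: zero IC on both sides
        return 0.0
    value = 2.0 * log_anc / denom
    return float(min(1.0, max(0.0, value)))
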