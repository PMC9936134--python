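"""Deterministic generators for benchmarking and testing the pipeline.

Two generators: a planted-block expression matrix (latent sample
profiles shared within a block plus independent Gaussian noise, giving a
controllable within-block Pearson correlation) and a matching toy GO
ontology whose per-block subtrees align the annotation structure with
the planted expression blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .ontology import AnnotationCorpus, GoDag, merge_annotations

__all__ = [
    "PlantedDesign",
    "make_planted_expression",
    "make_toy_ontology",
    "write_obo",
    "write_fixture",
]


@dataclass
class PlantedDesign:
    """Design of a planted-module expression dataset.

    ``within_block_corr`` is the expected Pearson correlation between two
    genes of the same block; ``noise_sd`` rescales the idiosyncratic
    noise around that target (1.0 keeps it exact). Genes listed in
    ``overlap_genes`` load on two consecutive blocks' latent profiles.
    """

    n_genes: int = 40
    n_samples: int = 60
    k_blocks: int = 4
    within_block_corr: float = 0.9
    noise_sd: float = 1.0
    overlap_genes: Sequence[int] = field(default_factory=tuple)
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.k_blocks < 1 or self.n_genes < 2 * self.k_blocks:
            raise ValueError("need k_blocks >= 1 and at least 2 genes per block")
        if not 0 < self.within_block_corr <= 1:
            raise ValueError("within_block_corr must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_planted_expression(design: PlantedDesign) -> tuple[ExpressionMatrix, np.ndarray]:
    """Block-correlated expression with known module labels.

    Gene g of block b is ``sqrt(r)·L_b + sqrt(1 − r)·noise_sd·eps_g``
    with L_b a block-shared standard-normal sample profile, so the
    expected within-block correlation is r/(r + (1 − r)·noise_sd²) = r at
    ``noise_sd = 1``. Overlap genes average two blocks' latents (variance
    renormalized). The matrix is shifted to be nonnegative, which leaves
    all correlations untouched.
    """
    rng = np.random.default_rng(design.seed)
    n, m, k = design.n_genes, design.n_samples, design.k_blocks
    r = design.within_block_corr
    latents = rng.standard_normal((k, m))
    labels = np.array([i * k // n for i in range(n)])  # near-equal blocks, in order
    values = np.empty((n, m))
    overlap = set(int(g) for g in design.overlap_genes)
    for i in range(n):
        b = labels[i]
        if i in overlap:
            b2 = (b + 1) % k
            shared = (latents[b] + latents[b2]) / np.sqrt(2.0)
        else:
            shared = latents[b]
        eps = rng.standard_normal(m)
        values[i] = np.sqrt(r) * shared + np.sqrt(1.0 - r) * design.noise_sd * eps
    values -= values.min()
    gene_ids = [f"G{i:04d}" for i in range(n)]
    sample_ids = [f"S{j:03d}" for j in range(m)]
    return ExpressionMatrix(gene_ids, sample_ids, values, units="fpkm"), labels


def make_toy_ontology(
    labels: Sequence[int],
    gene_ids: Sequence[str] | None = None,
    terms_per_block: int = 3,
    depth: int = 2,
    annotation_noise: float = 0.0,
    annotations_per_gene: int = 2,
    seed: int | None = 0,
) -> tuple[GoDag, AnnotationCorpus, dict[int, list[str]]]:
    """Toy GO DAG with one subtree per planted block, plus annotations.

    The DAG has a single root, one chain of ``depth`` intermediate terms
    per block, and ``terms_per_block`` leaves hanging off each chain's
    end. Genes of block b draw their annotations from subtree b's
    leaves; each annotation is independently redirected to a leaf of a
    different subtree with probability ``annotation_noise``.

    Returns the DAG, the propagated annotation corpus and the
    block → leaf-terms map.
    """
    labels = np.asarray(labels, dtype=int)
    blocks = sorted(set(labels.tolist()))
    if len(blocks) < 2:
        raise ValueError("need at least 2 blocks")
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(len(labels))]
    if terms_per_block < 1 or depth < 1:
        raise ValueError("terms_per_block and depth must be >= 1")
    rng = np.random.default_rng(seed)

    counter = 0

    def new_term() -> str:
        nonlocal counter
        counter += 1
        return f"GO:{counter:07d}"

    root = new_term()
    parents: dict[str, frozenset[str]] = {root: frozenset()}
    block2terms: dict[int, list[str]] = {}
    for b in blocks:
        parent = root
        for _ in range(depth):
            node = new_term()
            parents[node] = frozenset([parent])
            parent = node
        leaves = []
        for _ in range(terms_per_block):
            leaf = new_term()
            parents[leaf] = frozenset([parent])
            leaves.append(leaf)
        block2terms[b] = leaves
    dag = GoDag(parents, namespace="biological_process")

    rows = []
    for gene, b in zip(gene_ids, labels):
        own = block2terms[int(b)]
        n_ann = min(annotations_per_gene, len(own))
        chosen = rng.choice(len(own), size=n_ann, replace=False)
        for c in chosen:
            term = own[int(c)]
            if annotation_noise > 0 and rng.random() < annotation_noise:
                other = [x for x in blocks if x != b]
                foreign = block2terms[int(rng.choice(other))]
                term = foreign[int(rng.integers(len(foreign)))]
            rows.append((gene, term))
    corpus = merge_annotations([pd.DataFrame(rows, columns=["gene", "term"])], dag)
    return dag, corpus, block2terms


def write_obo(dag: GoDag, path) -> None:
    """Serialize a :class:`GoDag` as a minimal OBO 1.2 document."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n\n")
        for term in sorted(dag.parents):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: synthetic term {term}\n")
            fh.write(f"namespace: {dag.namespace}\n")
            for p in sorted(dag.parents[term]):
                fh.write(f"is_a: {p} ! synthetic term {p}\n")
            fh.write("\n")


def write_fixture(
    out_dir,
    design: PlantedDesign,
    terms_per_block: int = 3,
    depth: int = 2,
    annotation_noise: float = 0.0,
) -> dict[str, str]:
    """Write a complete synthetic dataset (expression TSV, OBO ontology,
    annotation TSV, truth labels) into ``out_dir``; returns the paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    X, labels = make_planted_expression(design)
    dag, corpus, _ = make_toy_ontology(
        labels,
        gene_ids=X.gene_ids,
        terms_per_block=terms_per_block,
        depth=depth,
        annotation_noise=annotation_noise,
        seed=design.seed,
    )
    paths = {
        "expression": os.path.join(out_dir, "expression.tsv"),
        "obo": os.path.join(out_dir, "ontology.obo"),
        "annotations": os.path.join(out_dir, "annotations.tsv"),
        "labels": os.path.join(out_dir, "truth_labels.tsv"),
    }
    X.to_dataframe().to_csv(paths["expression"], sep="\t")
    write_obo(dag, paths["obo"])
    ann_rows = [
        (gene, term)
        for gene, terms in sorted(corpus.gene2terms.items())
        for term in sorted(terms)
    ]
    pd.DataFrame(ann_rows).to_csv(paths["annotations"], sep="\t", header=False, index=False)
    pd.DataFrame({"gene": X.gene_ids, "block": labels}).to_csv(
        paths["labels"], sep="\t", index=False
    )
    return paths
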