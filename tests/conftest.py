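import numpy as np
import pytest

from gmigago import (
    DistanceMatrix,
    GoDag,
    PAMGA,
    PlantedDesign,
    distance_matrix,
    make_planted_expression,
    make_toy_ontology,
    merge_annotations,
)


@pytest.fixture(scope="session")
def planted_strong():
    """4 well-separated blocks of 10 genes, within-block r = 0.9."""
    design = PlantedDesign(
        n_genes=40, n_samples=60, k_blocks=4, within_block_corr=0.9, seed=1
    )
    X, labels = make_planted_expression(design)
    return X, labels


@pytest.fixture(scope="session")
def planted_strong_distance(planted_strong):
    X, _ = planted_strong
    return distance_matrix(X)


@pytest.fixture(scope="session")
def noisy_fixture():
    """Function-aligned fixture: moderate correlation, six genes planted in
    two blocks, annotations with 20% cross-subtree noise. Stage-1 clustering
    of this data leaves headroom for functional refinement."""
    design = PlantedDesign(
        n_genes=40,
        n_samples=60,
        k_blocks=4,
        within_block_corr=0.75,
        overlap_genes=(8, 9, 18, 19, 28, 29),
        seed=1,
    )
    X, labels = make_planted_expression(design)
    dag, corpus, block2terms = make_toy_ontology(
        labels, gene_ids=X.gene_ids, annotation_noise=0.2, seed=2
    )
    return X, labels, dag, corpus, block2terms


@pytest.fixture(scope="session")
def noisy_stage1(noisy_fixture):
    X, labels, dag, corpus, _ = noisy_fixture
    est = PAMGA(
        k=4, population_size=60, generations=10, pam_max_iter=400, random_state=7
    ).fit(X)
    return est


@pytest.fixture()
def toy_dag_corpus():
    """Hand-built DAG root -> {A, D}, A -> {B, C} with p(root)=1,
    p(A)=p(D)=0.5, p(B)=p(C)=0.25 under a 4-gene corpus."""
    import pandas as pd

    dag = GoDag(
        {
            "GO:0000001": frozenset(),
            "GO:0000002": frozenset(["GO:0000001"]),  # A
            "GO:0000003": frozenset(["GO:0000002"]),  # B
            "GO:0000004": frozenset(["GO:0000002"]),  # C
            "GO:0000005": frozenset(["GO:0000001"]),  # D
        }
    )
    ann = pd.DataFrame(
        [("g1", "GO:0000003"), ("g2", "GO:0000004"), ("g3", "GO:0000005"), ("g4", "GO:0000005")],
        columns=["gene", "term"],
    )
    corpus = merge_annotations([ann], dag)
    return dag, corpus


def random_distance_matrix(n: int, rng: np.random.Generator) -> DistanceMatrix:
    """A valid random gene-distance matrix derived from random expression."""
    values = rng.standard_normal((n, max(5, n // 2)))
    corr = np.corrcoef(values)
    D = np.clip(1 - corr, 0, 2)
    np.fill_diagonal(D, 0)
    D = (D + D.T) / 2
    return DistanceMatrix([f"g{i}" for i in range(n)], D)
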