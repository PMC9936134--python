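"""End-to-end two-stage estimator: co-expression clustering (PAM-GA)
followed by GO-driven overlapping-module refinement (FSO-GA)."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .fso_ga import FSOGA
from .ontology import AnnotationCorpus, GoDag
from .pam_ga import PAMGA

__all__ = ["GMIGAGO"]


class GMIGAGO(BaseEstimator):
    """Functional gene module identification.

    Runs :class:`PAMGA` on the expression matrix, then :class:`FSOGA` on
    the resulting partition. See those classes for parameter details;
    ``over`` and ``alpha`` are the dataset-dependent stage-2 knobs.

    Attributes (after fit)
    ----------------------
    stage1_ : the fitted :class:`PAMGA`.
    stage2_ : the fitted :class:`FSOGA`.
    k_, labels_, silhouette_ : stage-1 outputs.
    membership_, sim_, sig_, target_ : stage-2 outputs.
    """

    def __init__(
        self,
        dag: GoDag,
        corpus: AnnotationCorpus,
        over: float,
        alpha: float,
        k="scan",
        k_min: int = 8,
        k_max: int = 20,
        stage1_population: int = 200,
        stage2_population: int = 1000,
        generations: int = 20,
        mutation_rate: float = 0.1,
        patience: int = 3,
        alpha_sig: float = 0.05,
        top: int = 20,
        b_mode: str = "nearest_other",
        random_state=None,
    ):
        self.dag = dag
        self.corpus = corpus
        self.over = over
        self.alpha = alpha
        self.k = k
        self.k_min = k_min
        self.k_max = k_max
        self.stage1_population = stage1_population
        self.stage2_population = stage2_population
        self.generations = generations
        self.mutation_rate = mutation_rate
        self.patience = patience
        self.alpha_sig = alpha_sig
        self.top = top
        self.b_mode = b_mode
        self.random_state = random_state

    def fit(self, X, y=None):
        seeds = np.random.SeedSequence(self.random_state).spawn(2)
        stage1 = PAMGA(
            k=self.k,
            k_min=self.k_min,
            k_max=self.k_max,
            population_size=self.stage1_population,
            generations=self.generations,
            mutation_rate=self.mutation_rate,
            patience=self.patience,
            b_mode=self.b_mode,
            random_state=seeds[0].generate_state(1)[0] % (2**31),
        ).fit(X)
        stage2 = FSOGA(
            dag=self.dag,
            corpus=self.corpus,
            over=self.over,
            alpha=self.alpha,
            population_size=self.stage2_population,
            generations=self.generations,
            mutation_rate=self.mutation_rate,
            patience=self.patience,
            alpha_sig=self.alpha_sig,
            top=self.top,
            random_state=seeds[1].generate_state(1)[0] % (2**31),
        ).fit(stage1.distance_, medoids=stage1.medoids_, labels=stage1.assignment_)
        self.stage1_ = stage1
        self.stage2_ = stage2
        self.k_ = stage1.k_
        self.labels_ = stage1.labels_
        self.silhouette_ = stage1.silhouette_
        self.membership_ = stage2.membership_
        self.sim_ = stage2.sim_
        self.sig_ = stage2.sig_
        self.target_ = stage2.target_
        return self
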