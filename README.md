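# gmigago

Functional gene module identification from expression data. Most
co-expression module detectors (WGCNA-style pipelines and their
derivatives) cluster genes purely by expression similarity; the modules
they return are often functionally heterogeneous. `gmigago` identifies
**overlapping gene modules that are coherent both in expression and in
Gene Ontology (GO) function**, in two stages:

1. **PAM-GA** — Partitioning Around Medoids on the gene–gene distance
   `Dist(g₁, g₂) = 1 − r(g₁, g₂)` (Pearson correlation of expression
   profiles), with the random medoid search replaced by an
   elite-crossover genetic algorithm whose fitness is the mean
   silhouette `S = (1/n) Σᵢ sᵢ`, `sᵢ = (bᵢ − aᵢ)/max(aᵢ, bᵢ)`. The
   cluster count k is chosen by scanning a range (default 8–20) and
   keeping the k with the best silhouette.
2. **FSO-GA** — the partition is relaxed into a binary gene × module
   membership matrix A (a gene may belong to several modules). A gene
   may join any module whose medoid is closer than that module's
   box-plot outlier fence `Q3 + 1.5·(Q3 − Q1)` of member–medoid
   distances. A second genetic algorithm searches this constrained
   space, maximizing

   `Target = Sim · α + Sig`

   where `Sim` is the mean pairwise **Lin similarity**
   `sim(t₁, t₂) = 2·IC(MICA) / (IC(t₁) + IC(t₂))` among each module's
   significantly enriched biological-process terms (hypergeometric test,
   Benjamini–Hochberg adjusted p < 0.05, top 20 per module), and `Sig`
   aggregates `−log₁₀ p_adj` of those terms normalized by the module
   count. `over` (overlap probability) and `α` are dataset-dependent.

The package is organized as scikit-learn-style estimators — `PAMGA`,
`FSOGA`, and the end-to-end `GMIGAGO` — plus functional APIs for every
step (distances, silhouette, PAM, GO semantic similarity, enrichment)
and a `gmigago` command-line tool. A deterministic synthetic-data module
generates planted-block expression matrices with matched toy GO
ontologies, so the full pipeline is testable without downloads.

## Worked example

Simulate a 40-gene dataset with four planted co-expression blocks
(within-block r = 0.75, six genes shared between neighboring blocks) and
a matching toy ontology with 20% annotation noise, then run both stages:

```sh
gmigago simulate --out demo --n-genes 40 --n-samples 60 --blocks 4 \
    --corr 0.75 --overlap-genes 8,9,18,19,28,29 --annotation-noise 0.2 --seed 1
gmigago run-all --expression demo/expression.tsv --out demo_out \
    --k-min 2 --k-max 8 --population 200 --generations 20 --pam-max-iter 500 \
    --obo demo/ontology.obo --annotations demo/annotations.tsv \
    --over 1.0 --alpha 1000 --population2 100 --seed 7
```

prints

```
{"k": 4, "silhouette": 0.5727737687863678, "sim": 0.8398123255588841, "target": 851.1935887834286}
```

The silhouette scan recovered the planted k = 4; the GA medoid search
raised the mean silhouette over the plain PAM seed (0.5728 vs 0.5662,
see `demo_out/report.json`); and the functional refinement raised the
mean within-module term similarity Sim from 0.7629 (hard partition) to
0.8398 (`demo_out/report_stage2.json`) by reassigning the
expression-ambiguous genes to the modules that match their annotations
and overlapping them where warranted. `demo_out/membership.tsv` holds
the final gene × module matrix and `demo_out/enrichment.tsv` the
per-module enriched GO terms behind the scores.

The same thing in Python:

```python
from gmigago import GMIGAGO, load_expression, load_obo, merge_annotations

X = load_expression("demo/expression.tsv")
dag = load_obo("demo/ontology.obo")
corpus = merge_annotations(["demo/annotations.tsv"], dag)
model = GMIGAGO(dag, corpus, over=1.0, alpha=1000, k_min=2, k_max=8,
                random_state=7).fit(X)
model.k_, model.silhouette_, model.sim_, model.membership_
```

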