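# Methods

## Model and procedure

`gmigago` treats functional gene module identification as a two-stage
combinatorial optimization.

**Stage 1 (PAM-GA).** Genes are points under the distance
`Dist(g₁, g₂) = 1 − r(g₁, g₂)`, with `r` the sample Pearson correlation
of the two expression profiles across samples, so the distance lies in
[0, 2] and only positive co-expression counts as proximity. Clustering
is medoid-based (a cluster center is an actual gene), which is what
makes the arbitrary distance legal. Plain PAM here is: k-means++-style
seeding on the distance matrix, then random single-swap proposals
(medoid ↔ non-medoid, uniform) accepted only when they strictly reduce
the summed gene-to-medoid distance, up to `max_iter` proposals (default
2000). The cluster count k is chosen by running PAM for each k in
`[k_min, k_max]` (default 8–20) and keeping the k with the highest mean
silhouette; ties go to the smaller k, and that k is frozen for
everything downstream. The genetic algorithm then searches over medoid
sets: an individual is a k-subset of gene indices, fitness is the mean
silhouette of the induced nearest-medoid partition, crossover draws a
uniform k-subset of the union of parent and elite, and mutation (per
individual, probability μ) swaps one element for a uniformly chosen
outside gene. Because the PAM solution is seeded into the initial
population and the elite never regresses, the final silhouette is
bounded below by the PAM one on every run.

**Stage 2 (FSO-GA).** The hard partition is relaxed to a binary
membership matrix A (genes × modules). Candidate memberships come from
a box-plot rule: module j's threshold is `Q3 + 1.5·(Q3 − Q1)` over its
own members' distances to its medoid, and gene i may join module j iff
`Dist(i, medoid_j) < threshold_j` (strict, as defined); the gene's
stage-1 module is always allowed, so every gene has at least one
candidate. The GA individual is A itself. Initialization assigns each
gene to 1..Mᵢ of its candidates — with probability `over` to two or
more (when Mᵢ > 1), otherwise to exactly one; `over = 1` draws the
count uniformly from 1..Mᵢ. Crossover is single-point by gene rows;
mutation redraws a gene's row with probability μ. Fitness is
`Target = Sim·α + Sig` (details below). The stage-1 partition is seeded
into the population, so Target never falls below the partition's value.

**Elite-crossover GA engine.** Both stages share one loop: evaluate the
initial population, take the best as elite, and in each generation
cross every individual with the current elite, mutate, evaluate, and
let any strictly fitter child replace the elite immediately. Children
form the next generation. Termination: `generations` reached (default
20) or the elite fitness unchanged for `patience` (default 3)
consecutive generations, compared with exact equality — fitness is a
deterministic function of the individual. Fitness values are memoized
by a canonical key (sorted medoid tuple; raw bytes of A), which matters
in stage 2 where an evaluation entails per-module enrichment analyses;
per-module profiles and pairwise Lin values are additionally cached
across individuals keyed by the module's gene set.

## Functional scores

For each module, enrichment is a one-sided (upper-tail) hypergeometric
test of every GO biological-process term annotated — after propagating
annotations to all is_a ancestors — to at least one module gene,
against the universe of annotated genes in the analyzed dataset.
Benjamini–Hochberg adjustment runs across the module's tested terms;
terms with adjusted p < 0.05 are retained, truncated to the 20 smallest
(ties broken by term ID so truncation is deterministic).

Term similarity is Lin's information-content measure. `p(t)` is the
annotation frequency of t (propagated gene count over the count at the
namespace root), `IC(t) = −log p(t)`, and

`sim(t₁, t₂) = 2·IC(MICA) / (IC(t₁) + IC(t₂))`,

with the MICA the common ancestor (each term counts as its own
ancestor) of smallest p. A tempting mis-reading of the formula takes
the *maximum* of `log p(t)` over shared ancestors, which — since
`log p ≤ 0` — would select the least informative ancestor (always the
root, giving 0) and defeat the measure's purpose; the standard MICA
form is the default and the max-log-p variant is kept behind
`mode="literal"` for auditability.

Given per-module retained terms, `Simᵢ` for term tᵢ is the mean Lin
similarity to the other retained terms of its module (modules with a
single retained term define no Simᵢ and contribute to Sig only), `Sim`
is the mean of all defined Simᵢ, and `Sig = (1/k) Σ −log₁₀ p_adj` over
all retained terms of all modules, normalized by the module count k as
defined (a per-term normalization is available via `sig_norm`).

## Parameters that matter

| Parameter | Default | Meaning |
| --- | --- | --- |
| `k_min..k_max` | 8–20 | silhouette scan range for the module count |
| `population_size` (stage 1) | 200 | GA population; 8000 is the large-dataset setting, 200 is the library default sized for desk-scale inputs |
| `population_size` (stage 2) | 1000 | stage-2 population; enrichment cost dominates, mitigated by memoization |
| `generations`, `patience` | 20, 3 | GA budget and stall rule |
| `mutation_rate` μ | 0.1 | per-individual (stage 1) / per-gene (stage 2) redraw probability |
| `over` | — | probability a gene with Mᵢ > 1 joins ≥ 2 modules; dataset-dependent, required |
| `alpha` α | — | weight of Sim against Sig in Target; dataset-dependent, required |
| `alpha_sig`, `top` | 0.05, 20 | enrichment significance cutoff and per-module term cap |
| `b_mode` | `nearest_other` | silhouette separation term (see below) |

`over` and α have no universal defaults by design: the CLI refuses to
run stage 2 without them. Typical values in practice are `over` ∈
{0.3, 1} and α ∈ {1000, 1800}; larger α pushes the search toward pure
functional similarity, larger `over` toward more inter-module overlap.

## Preprocessing

Expression input is a delimited genes × samples table. Raw counts are
converted to FPKM as `counts·10⁹ / (length_bp · total_counts)`. Genes
with zeros in more than `max_zero_fraction` (default 20%) of samples
are removed; a gene at exactly the cutoff is kept. Differential
expression selects genes with fold change (ratio of arithmetic group
means, no pseudocount, no log) ≥ x or ≤ 1/x and a two-sided two-sample
t-test p < 0.05; Student's equal-variance test is the default with
Welch behind a flag. A zero control mean with a nonzero case mean
counts as infinite fold change (passes the ≥ x arm); genes with both
means zero are excluded.

## Numerical choices and conventions

- Quartiles in the box-plot threshold use linear interpolation between
  order statistics (`numpy.percentile` default); fixed for
  reproducibility. Example: distances (1, 2, 3, 5) → Q1 = 1.75,
  Q3 = 3.5, threshold 6.125.
- Silhouette: the separation term bᵢ defaults to the nearest other
  cluster's mean distance (the standard definition, and what mainstream
  silhouette implementations compute); `pooled_other` (mean over all
  genes outside the cluster) is available and property-tested, since
  verbal definitions of bᵢ are sometimes pooled. Singleton clusters
  score sᵢ = 0 by convention.
- Nearest-medoid ties break toward the earliest medoid position; a
  medoid always owns its cluster even when tied at distance 0 with an
  earlier medoid, keeping clusters non-empty.
- A module emptied by stage-2 crossover or mutation is repaired by
  re-adding, among genes listing that module, the one closest to its
  medoid (deterministic).
- Constant expression rows are rejected (Pearson undefined); zero
  control variance in the t-test yields p = NaN and the gene is not
  selected.
- Enrichment p-values are floored at 1e-300 before `−log₁₀`.
- All randomness flows from user-supplied seeds through
  `numpy.random.Generator`; runs are bit-reproducible, and the CLI's
  outputs are byte-identical across same-seed reruns.

## Synthetic data: what it emulates and what it does not

`make_planted_expression` draws one latent standard-normal sample
profile per block; gene g of block b is
`√r·L_b + √(1−r)·noise_sd·ε`, giving expected within-block Pearson
correlation r at `noise_sd = 1` and ≈ 0 across blocks. Overlap genes
load on two blocks' latents (variance renormalized). The matrix is
shifted to be nonnegative, which leaves correlations untouched.
`make_toy_ontology` builds a single-root DAG with one intermediate
chain (`depth`) and `terms_per_block` leaves per block, annotates each
gene to leaves of its own block's subtree, and redirects each
annotation cross-subtree with probability `annotation_noise`.

This captures the structural assumptions the method relies on —
block-correlated expression, functionally coherent groups, annotation
noise, genes genuinely shared between modules — but not the marginal
distributions of real RNA-seq (skewness, heteroscedastic counts,
library-size effects), nor the scale and shape of the real GO DAG
(tens of thousands of terms, multiple parents, part_of relations).
Passing tests therefore demonstrate correctness of the algorithms and
recovery under the stated generative model, not performance claims on
any real dataset, where results also depend on the annotation snapshot
used.

## Problem sizes used in tests and the acceptance script

Fixtures are sized for exhaustive verifiability: 30-gene random
instances for silhouette oracles; toy DAGs ≤ 30 terms for Lin oracles;
backgrounds ≤ 25 for full hypergeometric enumeration; a 40-gene,
4-block, 60-sample planted dataset for recovery (within-block r = 0.9)
and for functional refinement (r = 0.75, six overlap genes, 20%
annotation noise); and a 12-gene, 3-module instance whose ~2000 legal
membership matrices are enumerated to confirm the GA attains the true
optimum. GA populations in these runs (40–200) are sized to the
fixtures; the library defaults (200 / 1000) and the large-dataset
setting (8000) are documented above. The synthetic fixtures — including
the stage-1 clustering that stage 2 refines — are pinned by fixed
generator seeds; user seeds drive the stochastic searches run on them.

## Known limitations

- Stage 2 optimizes the retained-term similarity, so it can favor
  "over-purified" modules whose weaker terms drop below significance;
  α trades this against Sig but the tension is inherent to the Target.
- Only is_a edges are used by default (part_of optional); molecular
  function and cellular component namespaces are filtered out rather
  than scored.
- The enrichment universe is the annotated genes of the analyzed
  dataset, the conventional self-contained choice; a web-service
  universe would differ.
- The GA is a heuristic: optimality is verified only on the enumerable
  instance; on larger inputs the guarantees are the monotone-improvement
  bounds (PAM-GA ≥ PAM, FSO-GA ≥ stage-1 partition).
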