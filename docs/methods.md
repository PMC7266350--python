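# Methods

## Model overview

The pipeline treats circRNA–disease association prediction as balanced
bipartite link prediction. Verified associations form a binary adjacency
matrix `AM` (rows circRNAs, columns diseases). Each candidate pair is
described by similarity context rather than by sequence or expression:
the circRNA side by a Gaussian interaction-profile (GIP) kernel row, the
disease side by a fused column of ontology semantics and GIP kernel. A
graph convolutional network trained with layer-wise Monte-Carlo sampling
turns those descriptors into lower-dimensional features, and a
penalized-attribute decision forest scores them.

The guiding assumption throughout is that functionally similar circRNAs
associate with similar diseases; every stage is a different encoding of
that prior.

## Similarities

**GIP kernel.** `K(i,j) = exp(-θ ‖V(i)-V(j)‖²)` with
`θ = 1 / mean(‖V‖²)` over the profiles being compared. The width
normalization averages over the number of profiles in the set (661 rows
for circRNAs, 100 columns for diseases at benchmark scale). The benchmark
description normalizes each axis by the *other* axis's count, which is
inconsistent with the index ranges of the sums it normalizes; the
`denominator` argument of `gip_width`/`gip_kernel` reproduces that
literal reading when wanted.

**Semantic similarity.** A disease `d`'s DAG is its ancestor closure in
the hierarchy. SV1 gives ancestor `s` the contribution
`D_d(s) = max(μ·D_d(s'))` over children `s'` in the DAG (`D_d(d)=1`),
with semantic contribution factor μ = 0.5; similarity is shared
contribution mass normalized by the two semantic values `DV`. SV2
replaces contributions in the numerator with information content
`D'(s) = -log(num DAGs containing s / num diseases in the hierarchy)`
(natural log by default, configurable) while keeping the SV1 denominator.
As defined, SV2 is therefore not bounded by 1 for rare shared ancestors;
it is computed as defined, with an optional clip (off by default). A
disease appearing at several hierarchy positions contributes the union of
its ancestor closures.

**Fusion.** `DSim = (SV1+SV2)/2` where both diseases occur in the
hierarchy, `GD` otherwise; `RSim = GC`. The pair descriptor is
`[RSim row i, DSim column j]`, length `n_circ + n_disease`.

## Sampled graph convolution

Descriptors are nodes of a kNN graph (cosine similarity, k = 10, union
symmetrization, self-loops, symmetric degree normalization
`D^{-1/2}(A+I)D^{-1/2}`). How to define a graph over candidate pairs is
genuinely open; the kNN construction was chosen because it makes no use
of labels and is isolated behind `build_sample_graph` so alternatives
(shared-circRNA edges, shared-disease edges) can be swapped in.
Per-column standardization and per-half norm balancing of descriptors
were evaluated as graph inputs; both helped one evaluation protocol and
hurt the other, so raw descriptors are kept.

Each layer `h^{(l+1)}(v) = σ(Σ_u Â(v,u) h^{(l)}(u) W^{(l)})` is read as an
expectation over nodes and estimated during training with `t_l` i.i.d.
draws from a proposal `q`, importance-weighted by `1/(t_l q(u))`. The
estimator's expectation equals the exact layer (verified by a 10^4-draw
test); drawing every node once with uniform `q` reproduces it exactly.
The default proposal is `q(u) ∝ ‖Â(:,u)‖²`. This reduces variance when
kernel mass concentrates on high-degree hubs — the regime the proposal is
designed for — but is *not* uniformly variance-reducing: for diffuse
off-hub mass it over-concentrates relative to the optimal
`|column|`-proportional proposal and can exceed uniform-sampling
variance. The tests exercise the hub-concentrated regime.

Architecture and training defaults (none dictated by the problem; all in
`GcnConfig`): one hidden layer of 64 ReLU units, softmax output,
`t_0 = t_1 = 256`, batch 256, 200 epochs, Adam with learning rate 0.01,
Glorot initialization, fixed seed. Gradients are hand-derived for the
two-matrix chain and verified against finite differences in the tests.
Evaluation is transductive: all fold nodes are graph nodes, but only
training-fold labels enter the loss (verified by a label-blindness test).
Extracted features are the penultimate-layer activations of an exact
(non-sampled) forward pass; the degenerate single-layer model returns the
input descriptors.

## Forest-PA

Bagged CART trees (Gini gain, binary splits at midpoints, numeric
attributes only) whose split criterion is *merit* = gain × attribute
weight. After each tree, attributes it tested draw a fresh weight
uniformly from the level range `WR(λ)` — `[0, e^{-1}]` at the root,
`[e^{-1/(λ-1)}+ρ, e^{-1/λ}]` deeper — using their smallest tested level;
untested attributes recover toward 1 by a stored increment
`(1 - weight_at_draw)/n_trees`. The analytic range bounds cross at deep
levels for any fixed ρ (the gap shrinks like 1/λ²); collapsed intervals
degenerate to the single point `e^{-1/λ}`, i.e. deep-level tests are
effectively unpenalized. Defaults: 100 trees, ρ = 0.01, unlimited depth,
minimum leaf 2. Ties break to the lowest attribute index, then the
lowest threshold, making trees deterministic given the bootstrap. With
penalties off the forest is exactly bagging of CART trees (checked
tree-for-tree against an independent reference implementation).
Prediction averages leaf class distributions.

## Evaluation protocols

Balanced datasets draw as many unverified pairs (without replacement) as
verified ones; negatives are drawn once per experiment and the set is
then split into stratified folds (plain random folds risk single-class
folds at small n). Metrics use a 0.5 score threshold, with 0 returned on
degenerate denominators (including MCC); fold aggregation reports mean ±
sample standard deviation (ddof = 1). AUC uses the trapezoidal rule with
rank-averaged ties.

Two protocols are provided for the similarity stage under
cross-validation:

* **leakage-free (library default):** GIP kernels are recomputed per fold
  from the training positives only (test-pair cells zeroed), so test
  labels never reach the features;
* **benchmark protocol (`transductive_gip=True`):** similarities are
  computed once from the full matrix, matching how the original
  evaluation appears to have been run.

The per-disease ranking mode trains on all verified pairs plus a fresh
balanced negative draw (seeded), adds every unlinked pair of the query
disease as an unlabelled graph node, and returns candidates in descending
score order.

## Synthetic benchmark

The generator emulates the two input files. Associations: circRNAs and
diseases are partitioned into blocks; within-block cells are Bernoulli
(`within_density` = 0.35), others Bernoulli(`background_density` = 0.02).
Hierarchy: a balanced skeleton tree (branching 2, depth 3) with
same-block diseases attached to a shared parent, so semantic similarity
agrees with the planted blocks. Defaults: 120 circRNAs, 30 diseases,
4 blocks — small enough for a full 5-fold run in well under a minute on
one CPU while keeping several hundred positives.

What the generator does *not* emulate: the heavy-tailed degree
distributions of curated databases, correlated ascertainment (well-studied
diseases accumulate associations), and any finer-than-block structure.
Because edges are drawn independently per cell, block membership is a
sufficient statistic: the Bayes-optimal ranking of held-out cells is the
block indicator, whose AUC on the default spec is ≈ 0.84 (balanced
negatives include within-block zero cells, and background edges create
cross-block positives). Pipeline results on this benchmark should be read
against that ceiling, not against 1.0, and passing it demonstrates signal
recovery — not performance on real curated data. Under the benchmark
(full-matrix) protocol the features additionally reflect held-out test
cells, which lifts measured AUC above the leakage-free ceiling; that gap
is itself informative about the original evaluation design.

## Numerical and interface choices

* Kernel matrices are symmetrized and their diagonals pinned to 1 to
  remove floating-point round-off.
* The kNN graph always contains self-loops, so isolated nodes cannot
  occur; `k` is clamped to `n-1` in the pipeline for tiny inputs.
* Edge-list and hierarchy dialects are UTF-8 TSV; a header row is
  recognized by a small vocabulary of column names; a single-column
  hierarchy row declares an isolated root disease.
* All indices are 0-based internally; identifiers are the external
  interface. Duplicate pairs collapse; duplicate ids are rejected.
* Every stochastic step (negative draw, fold split, GCN init/sampling,
  bootstrap, weight refresh) is seeded; experiment-level seeds are
  expanded with `SeedSequence` so stages are independent but reproducible.

## Limitations

* Identifiers must match between the association and hierarchy files; no
  MeSH XML parsing or name normalization.
* The GCN is plain NumPy: single-CPU, no sparse kernels; fine at the
  10^3-node scale this pipeline targets, not meant for much larger graphs.
* SV2's unbounded numerator means fused disease similarities can exceed 1
  when rare ancestors are shared (clip flag available).
* Competing methods, alternative classifiers and literature validation of
  ranked candidates are out of scope; the classifier seam
  (`train_forest`/`predict_proba`) is the intended extension point.
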