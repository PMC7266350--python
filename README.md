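# circgcn

Predicting circRNA–disease associations from a verified association list,
by fusing similarity information, extracting features with a sampled graph
convolutional network, and scoring candidate pairs with a
Forest-by-Penalizing-Attributes classifier.

## The problem

Circular RNAs (circRNAs) are covalently closed non-coding RNAs implicated
in cancers, diabetes and neurological disease, but experimentally linking
a circRNA to a disease is slow and expensive. Given a curated list of
verified circRNA–disease associations (a bipartite graph, e.g. 739 pairs
over 661 circRNAs and 100 diseases) the task is to rank the unverified
pairs so that true-but-undiscovered associations surface at the top.

## The method

1. **Interaction-profile kernels.** Each circRNA (matrix row) and disease
   (matrix column) gets a Gaussian interaction-profile kernel similarity
   `K(i,j) = exp(-θ‖V(i)-V(j)‖²)` with `θ` the reciprocal mean squared
   profile norm.
2. **Ontology semantics.** Diseases sitting in a MeSH-style DAG get two
   semantic similarities over shared ancestors: SV1 decays each ancestor's
   contribution by μ = 0.5 per level; SV2 weights ancestors by information
   content `-log(frequency across disease DAGs)`. The fused disease
   similarity is `(SV1+SV2)/2` where both diseases are covered by the
   hierarchy, and the GIP kernel otherwise.
3. **Fusion descriptors.** A candidate pair (circRNA *i*, disease *j*) is
   the concatenation of row *i* of the circRNA similarity and column *j*
   of the fused disease similarity.
4. **Sampled GCN.** Descriptors become nodes of a kNN sample graph; graph
   convolution layers, read as integral transforms over nodes, are trained
   by Monte-Carlo importance sampling (node distribution ∝ squared kernel
   column norms). Penultimate activations are the extracted features.
5. **Forest-PA.** A bagged CART forest whose split criterion is damped by
   per-attribute weights drawn from level-dependent ranges
   (`[0, e^{-1}]` at the root, `[e^{-1/(λ-1)}+ρ, e^{-1/λ}]` deeper),
   refreshed after every tree — trading a little individual tree accuracy
   for ensemble diversity.

Evaluation is balanced 5-fold cross-validation (equal numbers of verified
pairs and down-sampled unverified pairs) reporting accuracy, sensitivity,
precision, F1, Matthews correlation and ROC-AUC, plus a per-disease
candidate-ranking mode.

## Worked example

```bash
python examples/01_similarity_fusion.py
```

prints, for a 2×2 identity association matrix and the disease chain
A ← B ← C:

```
GIP width theta (circRNA axis): 1.0
circRNA GIP kernel:
 [[1.     0.1353]
 [0.1353 1.    ]]
SV1(A,B) = 0.6  (shared ancestor mass / total semantic value)
SV2(A,B) = 0.0  (zero: the only shared term is the root, IC 0)
fused disease similarity:
 [[0.5    0.3   ]
 [0.3    0.6352]]
descriptor for pair (c1, A): [1.     0.1353 0.5    0.3   ]
```

The two circRNA profiles differ in two positions with kernel width 1, so
their similarity is `exp(-2) ≈ 0.1353`; diseases A and B share ancestor A,
giving SV1 = (1+0.5)/(1+1.5) = 0.6, and the fused entry (0.6+0)/2 = 0.3.

`examples/05_cross_validation.py` runs the whole pipeline on a small
planted-block synthetic benchmark (40 circRNAs × 12 diseases, two blocks)
and prints a per-fold metric table with mean AUC ≈ 0.79 — well above the
0.5 chance level, showing the planted signal is recovered.

A thin CLI mirrors the library:

```bash
circgcn simulate --out-dir data --seed 1
circgcn cv data/associations.tsv --hierarchy data/hierarchy.tsv --seed 1
circgcn rank data/associations.tsv D000 --hierarchy data/hierarchy.tsv
```

## Layout

- `src/circgcn/` — `datasets` (edge lists, balanced sampling, folds),
  `mesh` (ontology semantics), `gip` (kernels), `fusion` (descriptors),
  `fastgcn` (sampled GCN), `forest_pa` (classifier), `evaluation`
  (CV + ranking), `synthetic` (generators), `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — model assumptions, parameter defaults, numerical
  choices and limitations.
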