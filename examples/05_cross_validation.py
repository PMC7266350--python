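"""5-fold cross-validation on a small planted-block benchmark.

Generates a synthetic association matrix (two circRNA/disease blocks;
within-block pairs associate at 0.5, background 0.03) plus a matching
hierarchy, then runs the full pipeline per fold: GIP + semantic fusion,
sampled-GCN feature extraction, Forest-PA scoring.  Uses a reduced
configuration so the example finishes in seconds.
"""

import circgcn as cg

spec = cg.SyntheticSpec(
    n_circ=40, n_dis=12, n_blocks=2, within_density=0.5,
    background_density=0.03, seed=7,
)
am, truth = cg.gen_associations(spec)
h = cg.gen_hierarchy(spec)
print(f"benchmark: {am.n_circ} circRNAs x {am.n_disease} diseases, "
      f"{am.n_positive} verified pairs")

config = cg.PipelineConfig(
    hidden_dims=(16,), sample_sizes=(64, 64), batch_size=64,
    epochs=30, n_trees=20, knn_k=6,
)
report = cg.cross_validate(am, h, config, seed=3)
print(report.per_fold.round(3))
print("mean AUC: %.3f  (planted signal recovered well above the 0.5 chance level)"
      % report.mean["auc"])
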