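"""Forest-PA: attribute penalization buys tree diversity.

Attributes used in the latest tree are damped for the next one, so the
forest spreads its splits over more attributes than plain bagging while
keeping accuracy.
"""

import numpy as np

from circgcn import predict_proba, train_forest, weight_range

print("weight range at the root level:", weight_range(1, 0.01))
print("weight range at level 2:      ", tuple(round(v, 4) for v in weight_range(2, 0.01)))

rng = np.random.default_rng(0)
x = rng.normal(size=(300, 6))
y = ((x[:, 0] + 0.8 * x[:, 1] + 0.6 * x[:, 2]) > 0).astype(int)
x_test = rng.normal(size=(200, 6))
y_test = ((x_test[:, 0] + 0.8 * x_test[:, 1] + 0.6 * x_test[:, 2]) > 0).astype(int)

for penalize in (False, True):
    forest = train_forest(x, y, n_trees=25, seed=1, penalize=penalize)
    roots = sorted({t.feature[0] for t in forest.trees})
    acc = ((predict_proba(forest, x_test)[:, 1] >= 0.5) == y_test).mean()
    label = "penalized" if penalize else "plain bagging"
    print(f"{label:14s} root attributes used: {roots}  holdout accuracy: {acc:.3f}")
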