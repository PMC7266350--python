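"""Forest by Penalizing Attributes (Forest-PA).

A bagged decision forest in which the split criterion of each CART tree is
damped by per-attribute weights.  Attributes that were tested in the most
recent tree receive a fresh random weight drawn from a level-dependent
range

    WR(lambda) = [0, e^{-1}]                       if lambda = 1 (root)
               = [e^{-1/(lambda-1)} + rho, e^{-1/lambda}]  if lambda > 1

so an attribute used near the root is penalized hardest; attributes absent
from the latest tree recover toward weight 1 by a per-attribute increment.
Splits are chosen by maximum *merit* = Gini gain x attribute weight, which
trades a little individual accuracy for diversity across trees.

Numeric attributes only; binary splits at midpoints between consecutive
distinct values; ties broken by lowest attribute index, then lowest
threshold.  Prediction averages per-tree leaf class distributions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AttributeWeightState",
    "PaTree",
    "PaForest",
    "weight_range",
    "merit",
    "build_tree",
    "update_weights",
    "train_forest",
    "predict_proba",
    "forest_to_json",
    "forest_from_json",
]


def weight_range(lam: int, rho: float) -> tuple[float, float]:
    """Weight interval for an attribute tested at tree level ``lam`` (root = 1)."""
    if lam < 1:
        raise ValueError("level lambda must be >= 1")
    if rho <= 0:
        raise ValueError("separation constant rho must be positive")
    hi = math.exp(-1.0 / lam)
    if lam == 1:
        return (0.0, hi)
    lo = math.exp(-1.0 / (lam - 1)) + rho
    if lo > hi:
        raise ValueError(
            f"empty weight range at level {lam}: rho={rho} too large "
            f"({lo:.6f} > {hi:.6f})"
        )
    return (lo, hi)


def merit(gain: float, weight: float) -> float:
    """Penalized split quality: classification ability times attribute weight."""
    if gain < 0:
        raise ValueError("gain must be nonnegative")
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    return gain * weight


@dataclass
class AttributeWeightState:
    """Per-attribute weights and weight increments between trees."""

    weight: np.ndarray
    increment: np.ndarray
    rho: float = 0.01
    n_trees: int = 100  # horizon of the linear recovery schedule

    @classmethod
    def initial(cls, n_attributes: int, rho: float = 0.01, n_trees: int = 100) -> "AttributeWeightState":
        return cls(
            weight=np.ones(n_attributes),
            increment=np.zeros(n_attributes),
            rho=rho,
            n_trees=n_trees,
        )


@dataclass
class PaTree:
    """CART tree stored as flat arrays; feature -1 marks a leaf."""

    feature: list[int] = field(default_factory=list)
    threshold: list[float] = field(default_factory=list)
    left: list[int] = field(default_factory=list)
    right: list[int] = field(default_factory=list)
    dist: list[list[float]] = field(default_factory=list)
    tested_attribute_levels: dict[int, int] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Leaf class distribution for every row of ``x``."""
        x = np.asarray(x, dtype=float)
        n_classes = len(self.dist[0])
        out = np.empty((x.shape[0], n_classes))
        stack = [(0, np.arange(x.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if idx.size == 0:
                continue
            f = self.feature[node]
            if f < 0:
                out[idx] = self.dist[node]
            else:
                go_left = x[idx, f] <= self.threshold[node]
                stack.append((self.left[node], idx[go_left]))
                stack.append((self.right[node], idx[~go_left]))
        return out


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def _best_splits_per_feature(
    x: np.ndarray, y: np.ndarray, n_classes: int, min_leaf: int
) -> tuple[np.ndarray, np.ndarray]:
    """Best Gini gain and threshold per feature (vectorized threshold sweep).

    Returns (gains, thresholds); gain is -inf where no valid split exists.
    Within a feature, equal gains resolve to the lowest threshold.
    """
    n, f = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    xs = np.take_along_axis(x, order, axis=0)
    ys = y[order]  # n x f
    onehot = ys[:, :, None] == np.arange(n_classes)[None, None, :]
    cum = np.cumsum(onehot, axis=0).astype(float)  # n x f x c
    total = cum[-1]  # f x c
    parent_gini = 1.0 - ((total / n) ** 2).sum(axis=1)  # per feature (all equal)

    left = cum[:-1]  # (n-1) x f x c, split after position i (left size i+1)
    right = total[None, :, :] - left
    nl = np.arange(1, n, dtype=float)[:, None]
    nr = n - nl
    gini_l = 1.0 - (left**2).sum(axis=2) / nl**2
    gini_r = 1.0 - (right**2).sum(axis=2) / nr**2
    weighted = (nl * gini_l + nr * gini_r) / n
    gain = parent_gini[None, :] - weighted

    valid = (xs[:-1] < xs[1:]) & (nl >= min_leaf) & (nr >= min_leaf)
    gain = np.where(valid, gain, -np.inf)
    pos = np.argmax(gain, axis=0)  # first max -> lowest threshold
    feat_idx = np.arange(f)
    best_gain = gain[pos, feat_idx]
    thresholds = 0.5 * (xs[pos, feat_idx] + xs[pos + 1, feat_idx])
    return best_gain, thresholds


def build_tree(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    n_classes: int | None = None,
    max_depth: int | None = None,
    min_leaf: int = 2,
) -> PaTree:
    """Grow a CART tree choosing splits by maximum merit (gain x weight).

    Deterministic: ties break to the lowest attribute index, then the
    lowest threshold.  Growth stops at pure nodes, ``min_leaf`` per child,
    or ``max_depth`` levels.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if x.size == 0 or x.ndim != 2:
        raise ValueError("training data must be a nonempty 2-D array")
    if n_classes is None:
        n_classes = int(y.max()) + 1
    weights = np.asarray(weights, dtype=float)
    tree = PaTree()

    def add_leaf(counts: np.ndarray) -> int:
        node = tree.n_nodes
        tree.feature.append(-1)
        tree.threshold.append(0.0)
        tree.left.append(-1)
        tree.right.append(-1)
        tree.dist.append((counts / counts.sum()).tolist())
        return node

    def grow(idx: np.ndarray, depth: int) -> int:
        counts = np.bincount(y[idx], minlength=n_classes).astype(float)
        pure = (counts > 0).sum() <= 1
        too_deep = max_depth is not None and depth >= max_depth
        if pure or too_deep or idx.size < 2 * min_leaf:
            return add_leaf(counts)
        gains, thresholds = _best_splits_per_feature(
            x[idx], y[idx], n_classes, min_leaf
        )
        finite = np.isfinite(gains)
        merits = np.where(finite, gains * weights, -np.inf)
        best_f = int(np.argmax(merits))  # first max -> lowest attribute index
        if not np.isfinite(merits[best_f]) or gains[best_f] <= 0.0:
            return add_leaf(counts)
        thr = float(thresholds[best_f])
        level = depth + 1  # lambda: root split has level 1
        prev = tree.tested_attribute_levels.get(best_f)
        if prev is None or level < prev:
            tree.tested_attribute_levels[best_f] = level
        node = tree.n_nodes
        tree.feature.append(best_f)
        tree.threshold.append(thr)
        tree.left.append(-1)
        tree.right.append(-1)
        tree.dist.append((counts / counts.sum()).tolist())
        go_left = x[idx, best_f] <= thr
        tree.left[node] = grow(idx[go_left], depth + 1)
        tree.right[node] = grow(idx[~go_left], depth + 1)
        return node

    grow(np.arange(x.shape[0]), 0)
    return tree


def update_weights(
    state: AttributeWeightState, latest_tree: PaTree, rng: np.random.Generator
) -> AttributeWeightState:
    """Post-tree weight update.

    Attributes tested in the latest tree draw a fresh weight uniformly from
    the range of their smallest level and a new increment steering them
    back to 1 over the forest horizon; untested attributes recover by their
    stored increment, capped at 1.

    The analytic bounds cross for deep levels (the gap between e^{-1/lam}
    and e^{-1/(lam-1)} shrinks like 1/lam^2, so any fixed rho eventually
    exceeds it); such collapsed intervals degenerate to the single point
    e^{-1/lam} — the attribute is then effectively unpenalized, which
    matches the intent that deep-level tests are penalized least.
    """
    weight = state.weight.copy()
    increment = state.increment.copy()
    state_levels = latest_tree.tested_attribute_levels
    untested = np.ones(weight.size, dtype=bool)
    for attr, lam in sorted(state_levels.items()):
        hi = math.exp(-1.0 / lam)
        lo = 0.0 if lam == 1 else min(math.exp(-1.0 / (lam - 1)) + state.rho, hi)
        weight[attr] = rng.uniform(lo, hi)
        increment[attr] = (1.0 - weight[attr]) / state.n_trees
        untested[attr] = False
    weight[untested] = np.minimum(1.0, weight[untested] + increment[untested])
    return AttributeWeightState(
        weight=weight, increment=increment, rho=state.rho, n_trees=state.n_trees
    )


@dataclass
class PaForest:
    """Ordered ensemble of penalized CART trees."""

    trees: list[PaTree]
    n_classes: int
    seed: int
    rho: float

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def train_forest(
    x: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    rho: float = 0.01,
    seed: int = 0,
    penalize: bool = True,
    max_depth: int | None = None,
    min_leaf: int = 2,
) -> PaForest:
    """Bagged Forest-PA training.

    Each tree is grown on a bootstrap sample (same size, with replacement)
    using the current attribute weights, which start at 1 and are updated
    after every tree.  ``penalize=False`` pins all weights at 1, reducing
    the forest to plain bagging of CART trees.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    n_classes = int(y.max()) + 1
    rng = np.random.default_rng(seed)
    state = AttributeWeightState.initial(x.shape[1], rho=rho, n_trees=n_trees)
    trees: list[PaTree] = []
    n = x.shape[0]
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        tree = build_tree(
            x[boot],
            y[boot],
            weights=state.weight,
            n_classes=n_classes,
            max_depth=max_depth,
            min_leaf=min_leaf,
        )
        trees.append(tree)
        if penalize:
            state = update_weights(state, tree, rng)
    return PaForest(trees=trees, n_classes=n_classes, seed=seed, rho=rho)


def predict_proba(forest: PaForest, x: np.ndarray) -> np.ndarray:
    """Mean leaf class distribution across trees; rows sum to 1."""
    if not forest.trees:
        raise ValueError("forest has no trees; train it first")
    x = np.asarray(x, dtype=float)
    acc = np.zeros((x.shape[0], forest.n_classes))
    for tree in forest.trees:
        acc += tree.apply(x)
    return acc / forest.n_trees


def forest_to_json(forest: PaForest, path: str | Path | None = None) -> str:
    """Serialize a forest to a documented JSON structure (optionally to a file)."""
    payload = {
        "n_classes": forest.n_classes,
        "seed": forest.seed,
        "rho": forest.rho,
        "trees": [
            {
                "feature": t.feature,
                "threshold": t.threshold,
                "left": t.left,
                "right": t.right,
                "dist": t.dist,
                "tested_attribute_levels": {
                    str(k): v for k, v in t.tested_attribute_levels.items()
                },
            }
            for t in forest.trees
        ],
    }
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def forest_from_json(source: str | Path) -> PaForest:
    """Reload a forest serialized by :func:`forest_to_json`."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    payload = json.loads(text)
    trees = [
        PaTree(
            feature=t["feature"],
            threshold=t["threshold"],
            left=t["left"],
            right=t["right"],
            dist=t["dist"],
            tested_attribute_levels={int(k): v for k, v in t["tested_attribute_levels"].items()},
        )
        for t in payload["trees"]
    ]
    return PaForest(
        trees=trees,
        n_classes=payload["n_classes"],
        seed=payload["seed"],
        rho=payload["rho"],
    )
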