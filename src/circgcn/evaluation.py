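"""Cross-validation harness, classification metrics and candidate ranking.

The full pipeline per fold: recompute GIP kernels from the training fold's
positive associations (test-pair entries zeroed, so test labels never leak
into the features), fuse similarities into pair descriptors, build the
sample graph, train the sampled GCN on training-fold labels, extract
penultimate features, train Forest-PA on the training rows and score the
test rows.  Metrics follow the usual confusion-matrix definitions
(accuracy, sensitivity, precision, F1, Matthews correlation) at a 0.5
score threshold, plus ROC/AUC.

The ranking mode trains on all verified associations (plus a fresh
balanced negative draw) and orders every circRNA not yet linked to a query
disease by predicted score — the protocol used for prospective candidate
screening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .datasets import (
    AssociationMatrix,
    PairSample,
    kfold_split,
    make_balanced_dataset,
)
from .fastgcn import GcnConfig, build_sample_graph, extract_features, train_fastgcn
from .forest_pa import predict_proba, train_forest
from .fusion import FusedSimilarities, assemble_feature_table, build_dsim
from .gip import circ_profiles, disease_profiles, gip_kernel
from .mesh import DiseaseHierarchy, SemanticConfig, semantic_similarity_matrices

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CandidateRanking",
    "PipelineConfig",
    "metrics",
    "roc_auc",
    "confusion_from_scores",
    "cross_validate",
    "rank_candidates",
]

METRIC_NAMES = ["accuracy", "sensitivity", "precision", "f1", "mcc", "auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Per-fold metric table with mean and sample standard deviation rows."""

    per_fold: pd.DataFrame
    mean: dict[str, float]
    std: dict[str, float]


@dataclass
class CandidateRanking:
    """Score-ordered candidate circRNAs for one disease."""

    disease_id: str
    ranking: list[tuple[str, float]]  # (circRNA id, score), descending

    def top(self, n: int = 20) -> list[tuple[int, str, float]]:
        return [(r + 1, c, s) for r, (c, s) in enumerate(self.ranking[:n])]


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters (similarity, GCN, forest, evaluation)."""

    semantic: SemanticConfig = field(default_factory=SemanticConfig)
    knn_k: int = 10
    hidden_dims: tuple[int, ...] = (64,)
    sample_sizes: tuple[int, ...] = (256, 256)
    batch_size: int = 256
    epochs: int = 200
    learning_rate: float = 0.01
    sampling: str = "importance"
    n_trees: int = 100
    rho: float = 0.01
    max_depth: int | None = None
    min_leaf: int = 2
    n_folds: int = 5
    threshold: float = 0.5
    transductive_gip: bool = False
    literal_gip_width: bool = False

    def gcn_config(self, seed: int) -> GcnConfig:
        return GcnConfig(
            hidden_dims=self.hidden_dims,
            sample_sizes=self.sample_sizes,
            batch_size=self.batch_size,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            sampling=self.sampling,
            seed=seed,
        )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, precision, F1 and MCC from confusion counts.

    Degenerate denominators fall back to 0 (declared convention).
    """
    tp, tn, fp, fn = (float(v) for v in (c.tp, c.tn, c.fp, c.fn))
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else 0.0
    sen = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den else 0.0
    return {"accuracy": acc, "sensitivity": sen, "precision": prec, "f1": f1, "mcc": mcc}


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC (trapezoidal; ties handled by rank-averaging)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return points, auc


def confusion_from_scores(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    labels = np.asarray(labels)
    pred = np.asarray(scores) >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _fused_similarities(
    am_matrix: np.ndarray,
    sv1_m: np.ndarray,
    sv2_m: np.ndarray,
    mask: np.ndarray,
    config: PipelineConfig,
) -> FusedSimilarities:
    """GIP kernels from an adjacency matrix plus the precomputed semantics."""
    circ_den = am_matrix.shape[1] if config.literal_gip_width else None
    dis_den = am_matrix.shape[0] if config.literal_gip_width else None
    gc = gip_kernel(circ_profiles(am_matrix), denominator=circ_den)
    gd = gip_kernel(disease_profiles(am_matrix), denominator=dis_den)
    dsim = build_dsim(sv1_m, sv2_m, gd.matrix, mask)
    return FusedSimilarities(rsim=gc.matrix, dsim=dsim, provenance=np.asarray(mask, bool))


def _score_nodes(
    x: np.ndarray,
    y: np.ndarray,
    train_mask: np.ndarray,
    config: PipelineConfig,
    gcn_seed: int,
    forest_seed: int,
) -> np.ndarray:
    """Graph -> GCN features -> Forest-PA; returns class-1 scores for all nodes."""
    k = min(config.knn_k, x.shape[0] - 1)
    graph = build_sample_graph(x, k=k, train_mask=train_mask)
    model = train_fastgcn(graph, y, config.gcn_config(seed=gcn_seed))
    feats = extract_features(model, graph)
    train_idx = np.flatnonzero(train_mask)
    forest = train_forest(
        feats[train_idx],
        y[train_idx],
        n_trees=config.n_trees,
        rho=config.rho,
        seed=forest_seed,
        max_depth=config.max_depth,
        min_leaf=config.min_leaf,
    )
    return predict_proba(forest, feats)[:, 1]


def cross_validate(
    am: AssociationMatrix,
    hierarchy: DiseaseHierarchy | None,
    config: PipelineConfig,
    seed: int,
    samples: Sequence[PairSample] | None = None,
    labels_override: np.ndarray | None = None,
    return_scores: bool = False,
):
    """Stratified k-fold cross-validation of the full pipeline.

    ``labels_override`` substitutes the sample labels fed to the learner
    and the metrics (e.g. a shuffled copy for a permutation control); the
    adjacency matrix handed to the GIP stage is always masked consistently
    with the *original* test-fold positives, so no label information leaks
    through the features either way.
    """
    neg_seed, fold_seed, *stage_seeds = _derive_seeds(seed, 2 + 2 * config.n_folds)
    if samples is None:
        samples = make_balanced_dataset(am, seed=neg_seed)
    folds = kfold_split(samples, k=config.n_folds, seed=fold_seed)
    labels = np.array([s.label for s in samples])
    eval_labels = labels if labels_override is None else np.asarray(labels_override)

    if hierarchy is not None:
        sv1_m, sv2_m, mask = semantic_similarity_matrices(
            am.disease_ids, hierarchy, config.semantic
        )
    else:
        n_d = am.n_disease
        sv1_m = np.zeros((n_d, n_d))
        sv2_m = np.zeros((n_d, n_d))
        mask = np.zeros((n_d, n_d), dtype=bool)

    rows = []
    all_scores = np.full(len(samples), np.nan)
    for fold in range(config.n_folds):
        test_idx = folds.test_indices(fold)
        train_mask = np.ones(len(samples), dtype=bool)
        train_mask[test_idx] = False

        am_fold = am.am.astype(float)
        if not config.transductive_gip:
            for t in test_idx:
                s = samples[t]
                am_fold[s.circ_index, s.disease_index] = 0
        sims = _fused_similarities(am_fold, sv1_m, sv2_m, mask, config)
        x, _ = assemble_feature_table(sims, samples)
        scores = _score_nodes(
            x,
            eval_labels,
            train_mask,
            config,
            gcn_seed=stage_seeds[2 * fold],
            forest_seed=stage_seeds[2 * fold + 1],
        )
        y_test = eval_labels[test_idx]
        s_test = scores[test_idx]
        all_scores[test_idx] = s_test
        fold_metrics = metrics(confusion_from_scores(y_test, s_test, config.threshold))
        _, auc = roc_auc(y_test, s_test)
        fold_metrics["auc"] = auc
        rows.append({"fold": fold, **fold_metrics})

    per_fold = pd.DataFrame(rows).set_index("fold")
    mean = {m: float(per_fold[m].mean()) for m in METRIC_NAMES}
    std = {m: float(per_fold[m].std(ddof=1)) for m in METRIC_NAMES}
    report = MetricsReport(per_fold=per_fold, mean=mean, std=std)
    if return_scores:
        return report, all_scores
    return report


def rank_candidates(
    am: AssociationMatrix,
    hierarchy: DiseaseHierarchy | None,
    disease_id: str,
    config: PipelineConfig,
    seed: int,
) -> CandidateRanking:
    """Rank all circRNAs not yet linked to ``disease_id`` by predicted score.

    The model is trained on every verified association plus a fresh
    balanced negative draw; candidate pairs join the sample graph as
    unlabelled nodes (transductive) and are scored by the trained forest.
    """
    if disease_id not in am.disease_ids:
        raise KeyError(f"unknown disease {disease_id!r}")
    j = am.disease_ids.index(disease_id)
    neg_seed, gcn_seed, forest_seed = _derive_seeds(seed, 3)
    train_samples = make_balanced_dataset(am, seed=neg_seed)
    trained_pairs = {(s.circ_index, s.disease_index): idx for idx, s in enumerate(train_samples)}

    candidate_rows = [i for i in range(am.n_circ) if am.am[i, j] == 0]
    samples = list(train_samples)
    node_of_candidate: dict[int, int] = {}
    for i in candidate_rows:
        key = (i, j)
        if key in trained_pairs:
            node_of_candidate[i] = trained_pairs[key]
        else:
            node_of_candidate[i] = len(samples)
            samples.append(PairSample(i, j, 0))

    if hierarchy is not None:
        sv1_m, sv2_m, mask = semantic_similarity_matrices(
            am.disease_ids, hierarchy, config.semantic
        )
    else:
        n_d = am.n_disease
        sv1_m = np.zeros((n_d, n_d))
        sv2_m = np.zeros((n_d, n_d))
        mask = np.zeros((n_d, n_d), dtype=bool)
    sims = _fused_similarities(am.am.astype(float), sv1_m, sv2_m, mask, config)
    x, y = assemble_feature_table(sims, samples)
    train_mask = np.zeros(len(samples), dtype=bool)
    train_mask[: len(train_samples)] = True
    scores = _score_nodes(
        x, y, train_mask, config, gcn_seed=gcn_seed, forest_seed=forest_seed
    )
    ranked = sorted(
        ((am.circ_ids[i], float(scores[node_of_candidate[i]])) for i in candidate_rows),
        key=lambda t: -t[1],
    )
    return CandidateRanking(disease_id=disease_id, ranking=ranked)
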