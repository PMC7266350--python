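"""Disease semantic similarity over an ontology DAG.

Diseases live in a MeSH-style hierarchy (child -> parent edges forming a
directed acyclic graph).  For a disease ``d`` the induced DAG is its
ancestor closure ``N_d`` (including ``d``).  Two semantic similarity models
are computed over shared ancestors:

* **SV1** (hierarchy model): each ancestor ``s`` contributes
  ``D_d(s) = mu^depth`` — 1 at the root ``d`` itself, decayed by the semantic
  contribution factor ``mu`` per level away from ``d`` (formally
  ``D_d(s) = max(mu * D_d(s'))`` over children ``s'`` of ``s`` inside the
  DAG).  Similarity is the shared contribution mass normalised by the two
  semantic values ``DV(d) = sum_s D_d(s)``.

* **SV2** (information-content model): an ancestor shared by few diseases is
  more informative.  Its contribution is
  ``D'(s) = -log(num DAGs containing s / num diseases)``; similarity keeps
  the SV1 denominator.  As defined, SV2 is not bounded by 1; an optional
  clip is provided and off by default.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "DiseaseHierarchy",
    "DiseaseDAG",
    "SemanticConfig",
    "load_hierarchy",
    "build_disease_dag",
    "contribution",
    "semantic_value",
    "sv1",
    "ic_contribution",
    "sv2",
    "semantic_similarity_matrices",
]


@dataclass(frozen=True)
class SemanticConfig:
    """Parameters of the semantic models.

    mu : semantic contribution factor in (0,1); decay per hierarchy level.
    log_base : base of the information-content logarithm (None = natural).
    clip_sv2 : clip SV2 into [0,1] (the model as defined can exceed 1).
    ic_num_diseases : override for the denominator of the information
        content; default is the number of diseases in the hierarchy.
    """

    mu: float = 0.5
    log_base: float | None = None
    clip_sv2: bool = False
    ic_num_diseases: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError("mu must lie in (0, 1)")

    def log(self, x: float) -> float:
        if self.log_base is None:
            return math.log(x)
        return math.log(x, self.log_base)


class DiseaseHierarchy:
    """Global child -> parent disease hierarchy (a DAG)."""

    def __init__(
        self,
        edges: set[tuple[str, str]],
        diseases: set[str] | None = None,
    ) -> None:
        self.edges = set(edges)
        self.diseases = set(diseases or set())
        for child, parent in self.edges:
            self.diseases.add(child)
            self.diseases.add(parent)
        g = nx.DiGraph()
        g.add_nodes_from(self.diseases)
        g.add_edges_from(self.edges)  # child -> parent direction
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("hierarchy contains a cycle")
        self._graph = g
        self._parents: dict[str, set[str]] = {
            d: set(g.successors(d)) for d in self.diseases
        }
        self._closure_cache: dict[str, frozenset[str]] = {}
        self._dag_count_cache: dict[str, int] | None = None

    def __contains__(self, disease: str) -> bool:
        return disease in self.diseases

    def parents(self, disease: str) -> set[str]:
        return self._parents[disease]

    def ancestor_closure(self, disease: str) -> frozenset[str]:
        """Transitive parent closure of ``disease`` plus itself (N_d)."""
        cached = self._closure_cache.get(disease)
        if cached is not None:
            return cached
        if disease not in self.diseases:
            raise KeyError(f"unknown disease {disease!r}")
        closure = frozenset(nx.descendants(self._graph, disease) | {disease})
        self._closure_cache[disease] = closure
        return closure

    def dag_count(self, disease: str) -> int:
        """Number of diseases whose ancestor closure contains ``disease``."""
        if self._dag_count_cache is None:
            counts = {d: 0 for d in self.diseases}
            for d in self.diseases:
                for s in self.ancestor_closure(d):
                    counts[s] += 1
            self._dag_count_cache = counts
        return self._dag_count_cache[disease]


@dataclass
class DiseaseDAG:
    """Ancestor-closure DAG of one disease: root d, nodes N_d, edges E_d."""

    root: str
    nodes: frozenset[str]
    edges: set[tuple[str, str]]

    def children_within(self, s: str) -> list[str]:
        """Children of ``s`` restricted to the DAG's node set."""
        return [c for (c, p) in self.edges if p == s]


def load_hierarchy(path: str | Path, delimiter: str = "\t") -> DiseaseHierarchy:
    """Load a hierarchy TSV with rows (child_id, parent_id).

    A row with a single non-empty column declares an isolated disease (a
    root with no parent).  A header row of known column names
    (child/parent, case-insensitive) is skipped.
    """
    path = Path(path)
    header_words = {"child", "parent", "child_id", "parent_id", "disease", "term"}
    edges: set[tuple[str, str]] = set()
    diseases: set[str] = set()
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            fields = [f.strip() for f in row if f.strip()]
            if not fields:
                continue
            if lineno == 1 and all(f.lower() in header_words for f in fields):
                continue
            if len(fields) == 1:
                diseases.add(fields[0])
            elif len(fields) == 2:
                edges.add((fields[0], fields[1]))
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 1 or 2 columns, got {row!r}"
                )
    return DiseaseHierarchy(edges, diseases)


def build_disease_dag(h: DiseaseHierarchy, d: str) -> DiseaseDAG:
    """Induced DAG of disease ``d``: its ancestor closure and internal edges."""
    if d not in h:
        raise KeyError(f"disease {d!r} not present in the hierarchy")
    nodes = h.ancestor_closure(d)
    edges = {(c, p) for (c, p) in h.edges if c in nodes and p in nodes}
    return DiseaseDAG(root=d, nodes=nodes, edges=edges)


def contribution(dag: DiseaseDAG, cfg: SemanticConfig) -> dict[str, float]:
    """Per-node semantic contribution D_d(s) within a disease DAG.

    D_d(d) = 1; for s != d, D_d(s) = max over children s' of s inside the
    DAG of mu * D_d(s').  Values lie in (0, 1].
    """
    if not dag.nodes:
        raise ValueError("empty DAG")
    memo: dict[str, float] = {}

    def value(s: str) -> float:
        if s == dag.root:
            return 1.0
        if s in memo:
            return memo[s]
        children = dag.children_within(s)
        # every non-root node of an ancestor closure has a child in the DAG
        memo[s] = cfg.mu * max(value(c) for c in children)
        return memo[s]

    return {s: value(s) for s in sorted(dag.nodes)}


def semantic_value(table: dict[str, float]) -> float:
    """Semantic value DV(d): total contribution mass of the disease's DAG."""
    if not table:
        raise ValueError("empty contribution table")
    return float(sum(table.values()))


def sv1(d_i: str, d_j: str, h: DiseaseHierarchy, cfg: SemanticConfig) -> float:
    """Hierarchy-based semantic similarity in [0, 1]; 1 iff identical DAGs."""
    dag_i = build_disease_dag(h, d_i)
    dag_j = build_disease_dag(h, d_j)
    t_i = contribution(dag_i, cfg)
    t_j = contribution(dag_j, cfg)
    shared = dag_i.nodes & dag_j.nodes
    num = sum(t_i[s] + t_j[s] for s in shared)
    den = semantic_value(t_i) + semantic_value(t_j)
    return float(num / den)


def ic_contribution(s: str, h: DiseaseHierarchy, cfg: SemanticConfig | None = None) -> float:
    """Information-content contribution D'(s) = -log(frequency of s across DAGs)."""
    cfg = cfg or SemanticConfig()
    if s not in h:
        raise KeyError(f"disease {s!r} not present in the hierarchy")
    n_total = cfg.ic_num_diseases or len(h.diseases)
    return -cfg.log(h.dag_count(s) / n_total)


def sv2(d_i: str, d_j: str, h: DiseaseHierarchy, cfg: SemanticConfig) -> float:
    """Information-content semantic similarity (>= 0, can exceed 1 as defined)."""
    dag_i = build_disease_dag(h, d_i)
    dag_j = build_disease_dag(h, d_j)
    shared = dag_i.nodes & dag_j.nodes
    num = sum(2.0 * ic_contribution(s, h, cfg) for s in shared)
    den = semantic_value(contribution(dag_i, cfg)) + semantic_value(
        contribution(dag_j, cfg)
    )
    value = float(num / den)
    if cfg.clip_sv2:
        value = min(value, 1.0)
    return value


def semantic_similarity_matrices(
    diseases: list[str], h: DiseaseHierarchy, cfg: SemanticConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SV1, SV2 and a coverage mask over an ordered disease list.

    mask[i, j] is True iff both diseases occur in the hierarchy; outside the
    mask the similarity entries are 0 and carry no meaning (the fusion rule
    falls through to the GIP kernel there).
    """
    cfg = cfg or SemanticConfig()
    n = len(diseases)
    sv1_m = np.zeros((n, n))
    sv2_m = np.zeros((n, n))
    covered = np.array([d in h for d in diseases], dtype=bool)
    mask = np.outer(covered, covered)

    idx = np.flatnonzero(covered)
    dags = {i: build_disease_dag(h, diseases[i]) for i in idx}
    tables = {i: contribution(dags[i], cfg) for i in idx}
    dvs = {i: semantic_value(tables[i]) for i in idx}
    ic = {
        s: ic_contribution(s, h, cfg)
        for s in set().union(*(dags[i].nodes for i in idx))
    } if len(idx) else {}

    for a, i in enumerate(idx):
        for j in idx[a:]:
            shared = dags[i].nodes & dags[j].nodes
            den = dvs[i] + dvs[j]
            s1 = sum(tables[i][s] + tables[j][s] for s in shared) / den
            s2 = sum(2.0 * ic[s] for s in shared) / den
            if cfg.clip_sv2:
                s2 = min(s2, 1.0)
            sv1_m[i, j] = sv1_m[j, i] = s1
            sv2_m[i, j] = sv2_m[j, i] = s2
    return sv1_m, sv2_m, mask
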