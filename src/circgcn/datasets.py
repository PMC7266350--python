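"""Association data handling: edge lists, adjacency matrix, balanced sampling, folds.

The benchmark input is a two-column delimited edge list of verified
circRNA-disease associations.  From it we build a binary adjacency matrix
``AM`` (rows = circRNAs, columns = diseases), draw an equal number of
unverified pairs as negatives (balanced down-sampling without replacement)
and split the resulting labelled pair set into stratified cross-validation
folds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "AssociationMatrix",
    "PairSample",
    "FoldAssignment",
    "ParseError",
    "load_associations",
    "associations_from_pairs",
    "write_associations",
    "sample_negatives",
    "make_balanced_dataset",
    "kfold_split",
    "write_dataset",
]

# Column names recognised as a header row in edge-list files (lowercased).
_HEADER_WORDS = {
    "circrna", "circ", "circ_id", "circrna_id", "rna", "rna_id",
    "disease", "disease_id", "dis", "dis_id", "label",
}


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


@dataclass
class AssociationMatrix:
    """Binary circRNA x disease adjacency matrix with id indexes.

    ``am[i, j] == 1`` iff circRNA ``circ_ids[i]`` has a verified association
    with disease ``disease_ids[j]``.
    """

    circ_ids: list[str]
    disease_ids: list[str]
    am: np.ndarray

    def __post_init__(self) -> None:
        self.am = np.asarray(self.am, dtype=np.int8)
        if self.am.shape != (len(self.circ_ids), len(self.disease_ids)):
            raise ValueError(
                f"matrix shape {self.am.shape} does not match "
                f"{len(self.circ_ids)} circRNAs x {len(self.disease_ids)} diseases"
            )
        if len(set(self.circ_ids)) != len(self.circ_ids):
            raise ValueError("duplicate circRNA ids")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease ids")
        if not np.isin(self.am, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")

    @property
    def n_circ(self) -> int:
        return len(self.circ_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)

    @property
    def n_positive(self) -> int:
        return int(self.am.sum())

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Row/column indices of all verified associations, row-major order."""
        rows, cols = np.nonzero(self.am)
        return list(zip(rows.tolist(), cols.tolist()))


@dataclass(frozen=True)
class PairSample:
    """One labelled circRNA-disease pair: label 1 = verified, 0 = sampled negative."""

    circ_index: int
    disease_index: int
    label: int


@dataclass
class FoldAssignment:
    """Assignment of every sample to one of ``k`` cross-validation folds."""

    fold_of_sample: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample != fold)


def _looks_like_header(fields: Sequence[str]) -> bool:
    return all(f.strip().lower() in _HEADER_WORDS for f in fields if f.strip())


def associations_from_pairs(pairs: Iterable[tuple[str, str]]) -> AssociationMatrix:
    """Build an adjacency matrix from (circRNA id, disease id) pairs.

    Ids are ordered by first appearance; duplicate pairs collapse to a single
    matrix entry.
    """
    circ_ids: list[str] = []
    disease_ids: list[str] = []
    circ_pos: dict[str, int] = {}
    dis_pos: dict[str, int] = {}
    entries: set[tuple[int, int]] = set()
    for c, d in pairs:
        if c not in circ_pos:
            circ_pos[c] = len(circ_ids)
            circ_ids.append(c)
        if d not in dis_pos:
            dis_pos[d] = len(disease_ids)
            disease_ids.append(d)
        entries.add((circ_pos[c], dis_pos[d]))
    am = np.zeros((len(circ_ids), len(disease_ids)), dtype=np.int8)
    for i, j in entries:
        am[i, j] = 1
    return AssociationMatrix(circ_ids, disease_ids, am)


def load_associations(path: str | Path, delimiter: str = "\t") -> AssociationMatrix:
    """Load a two-column edge list (circRNA id, disease id) into an adjacency matrix.

    Dialect: UTF-8 delimited text, two columns.  An optional header row is
    recognised when every field of the first row is a known column name
    (e.g. ``circrna``/``disease``, case-insensitive).  Blank lines are
    skipped; any other row without exactly two non-empty fields raises
    :class:`ParseError` naming the line.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not f.strip() for f in row):
                continue
            if lineno == 1 and _looks_like_header(row):
                continue
            fields = [f.strip() for f in row]
            if len(fields) != 2 or not all(fields):
                raise ParseError(
                    f"{path}:{lineno}: expected two non-empty columns, got {row!r}"
                )
            pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ParseError(f"{path}: no association rows found")
    return associations_from_pairs(pairs)


def write_associations(am: AssociationMatrix, path: str | Path) -> None:
    """Write verified pairs back out as a tab-delimited edge list with header."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("circrna\tdisease\n")
        for i, j in am.positive_pairs():
            fh.write(f"{am.circ_ids[i]}\t{am.disease_ids[j]}\n")


def sample_negatives(
    am: AssociationMatrix, n_neg: int, seed: int
) -> list[PairSample]:
    """Draw ``n_neg`` distinct unverified pairs (zero cells) without replacement."""
    if n_neg < 0:
        raise ValueError("n_neg must be nonnegative")
    rows, cols = np.nonzero(am.am == 0)
    n_zero = rows.size
    if n_neg > n_zero:
        raise ValueError(
            f"requested {n_neg} negatives but only {n_zero} unverified pairs exist"
        )
    if n_neg == 0:
        return []
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_zero, size=n_neg, replace=False)
    return [
        PairSample(int(rows[t]), int(cols[t]), 0) for t in np.sort(chosen)
    ]


def make_balanced_dataset(am: AssociationMatrix, seed: int) -> list[PairSample]:
    """Positives plus an equal number of sampled negatives (R+ union R-)."""
    n_pos = am.n_positive
    if n_pos == 0:
        raise ValueError("association matrix contains no verified pairs")
    positives = [PairSample(i, j, 1) for i, j in am.positive_pairs()]
    negatives = sample_negatives(am, n_pos, seed)
    return positives + negatives


def kfold_split(samples: Sequence[PairSample], k: int, seed: int) -> FoldAssignment:
    """Stratified k-fold assignment: per-fold label ratios match the whole set."""
    n = len(samples)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available samples")
    labels = np.array([s.label for s in samples])
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of_sample = np.empty(n, dtype=np.int64)
    dummy_x = np.zeros((n, 1))
    for fold, (_, test_idx) in enumerate(splitter.split(dummy_x, labels)):
        fold_of_sample[test_idx] = fold
    return FoldAssignment(fold_of_sample=fold_of_sample, k=k, seed=seed)


def write_dataset(
    am: AssociationMatrix,
    samples: Sequence[PairSample],
    folds: FoldAssignment | None,
    path: str | Path,
) -> None:
    """Write the balanced dataset as TSV (circ_id, disease_id, label[, fold])."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        header = "circrna\tdisease\tlabel"
        if folds is not None:
            header += "\tfold"
        fh.write(header + "\n")
        for idx, s in enumerate(samples):
            row = (
                f"{am.circ_ids[s.circ_index]}\t{am.disease_ids[s.disease_index]}"
                f"\t{s.label}"
            )
            if folds is not None:
                row += f"\t{int(folds.fold_of_sample[idx])}"
            fh.write(row + "\n")
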