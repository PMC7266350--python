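"""Similarity fusion and per-pair feature descriptors.

The circRNA similarity ``RSim`` is the circRNA GIP kernel.  The disease
similarity ``DSim`` prefers ontology semantics where available and falls
back to the disease GIP kernel:

    DSim(i, j) = (SV1(i, j) + SV2(i, j)) / 2   if both diseases are in the
                                               hierarchy (coverage mask)
               = GD(i, j)                      otherwise

A candidate pair (circRNA i, disease j) is described by the concatenation
[RSim row i, DSim column j]; for the benchmark scale that is a
661 + 100 = 761-dimensional fusion descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import PairSample

__all__ = ["FusedSimilarities", "build_dsim", "fuse", "assemble_feature_table"]


@dataclass
class FusedSimilarities:
    """RSim (circRNA) and DSim (disease) similarity matrices plus provenance.

    ``provenance`` is boolean: True where DSim came from the semantic
    models, False where it fell through to the GIP kernel.
    """

    rsim: np.ndarray
    dsim: np.ndarray
    provenance: np.ndarray

    @property
    def n_circ(self) -> int:
        return self.rsim.shape[0]

    @property
    def n_disease(self) -> int:
        return self.dsim.shape[0]


def build_dsim(
    sv1: np.ndarray, sv2: np.ndarray, gd: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Disease similarity: semantic average under the mask, GIP elsewhere."""
    sv1, sv2, gd, mask = (np.asarray(a) for a in (sv1, sv2, gd, mask))
    if not (sv1.shape == sv2.shape == gd.shape == mask.shape):
        raise ValueError(
            f"shape mismatch: SV1 {sv1.shape}, SV2 {sv2.shape}, "
            f"GD {gd.shape}, mask {mask.shape}"
        )
    return np.where(mask, (sv1 + sv2) / 2.0, gd)


def fuse(sims: FusedSimilarities, pair: tuple[int, int]) -> np.ndarray:
    """Fusion descriptor [RSim row i, DSim column j] for one candidate pair."""
    i, j = pair
    if not (0 <= i < sims.n_circ):
        raise IndexError(f"circRNA index {i} out of range")
    if not (0 <= j < sims.n_disease):
        raise IndexError(f"disease index {j} out of range")
    return np.concatenate([sims.rsim[i, :], sims.dsim[:, j]])


def assemble_feature_table(
    sims: FusedSimilarities, samples: Sequence[PairSample]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack fusion descriptors for a sample list; labels aligned row-wise."""
    n_feat = sims.n_circ + sims.n_disease
    if not samples:
        return np.empty((0, n_feat)), np.empty((0,), dtype=np.int64)
    ci = np.array([s.circ_index for s in samples])
    dj = np.array([s.disease_index for s in samples])
    x = np.hstack([sims.rsim[ci, :], sims.dsim[:, dj].T])
    y = np.array([s.label for s in samples], dtype=np.int64)
    return x, y
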