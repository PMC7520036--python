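"""Weighted, directed, modified-Jaccard dissimilarity between layers.

Two layers alpha and beta over the same cell types are compared edge by edge.
For every directed cell-type pair ``(i, j)`` where at least one of the two
layers has an edge, the per-edge score is the relative weight difference

    s_ij = |w_ij^alpha - w_ij^beta| / (w_ij^alpha + w_ij^beta)

(0 when both weights are zero), and the dissimilarity is the mean of s over
the union of the two edge sets:

    d(alpha, beta) = sum_ij s_ij / |E_alpha U E_beta|

This is a weighted generalisation of the Jaccard distance on directed edge
sets: an edge present in only one layer scores 1, a perfectly matched edge
scores 0, and on binarized layers d reduces exactly to the classical Jaccard
distance |symmetric difference| / |union|.  Consequently d is 0 iff the two
weight matrices coincide on their union, 1 iff the edge sets are disjoint,
and always within [0, 1].  Directionality matters: A->B and B->A are
different edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .errors import ConsistencyError, FormatError, ValidationError
from .multiplex import Layer, MultiplexNetwork

__all__ = [
    "DissimilarityMatrix",
    "layer_dissimilarity",
    "weight_matrix_dissimilarity",
    "pairwise_dissimilarity",
    "binarize",
    "read_dissimilarity_csv",
    "write_dissimilarity_csv",
]


@dataclass(frozen=True, eq=False)
class DissimilarityMatrix:
    """Symmetric L x L matrix of pairwise layer dissimilarities in [0, 1]."""

    values: np.ndarray
    pair_ids: Tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        L = len(self.pair_ids)
        if v.shape != (L, L):
            raise ValidationError(f"matrix shape {v.shape} does not match {L} pair ids")
        if not np.array_equal(v, v.T):
            raise ValidationError("dissimilarity matrix must be exactly symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("dissimilarity matrix must have a zero diagonal")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValidationError("dissimilarities must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "pair_ids", tuple(self.pair_ids))

    def __len__(self) -> int:
        return len(self.pair_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy ``pdist`` order."""
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.pair_ids)
        return pd.DataFrame(self.values.copy(), index=ids, columns=ids)


def weight_matrix_dissimilarity(wa: np.ndarray, wb: np.ndarray) -> float:
    """The modified-Jaccard dissimilarity of two raw weight matrices.

    Both matrices must already be validated and index the same cell types;
    this is the computational core shared by :func:`layer_dissimilarity` and
    the pattern-search module (where one side is a binary query matrix).
    """
    union = (wa > 0) | (wb > 0)
    n_union = int(np.count_nonzero(union))
    if n_union == 0:
        raise ValidationError("both matrices are empty; dissimilarity undefined")
    num = np.abs(wa - wb)[union]
    den = (wa + wb)[union]
    return float(np.sum(num / den) / n_union)


def layer_dissimilarity(alpha: Layer, beta: Layer) -> float:
    """Dissimilarity d(alpha, beta) in [0, 1] between two layers.

    Raises
    ------
    ConsistencyError
        The layers index different cell-type sets.
    """
    if alpha.cell_types != beta.cell_types:
        raise ConsistencyError(
            f"layers {alpha.pair_id!r} and {beta.pair_id!r} index different cell types"
        )
    return weight_matrix_dissimilarity(alpha.weights, beta.weights)


def pairwise_dissimilarity(net: MultiplexNetwork) -> DissimilarityMatrix:
    """All pairwise layer dissimilarities of a network.

    Each unordered pair is computed once and mirrored, so the result is
    symmetric bit-for-bit and the diagonal is exactly zero.
    """
    L = len(net)
    if L < 2:
        raise ValidationError(f"need at least 2 layers to compare, got {L}")
    values = np.zeros((L, L))
    layers = net.layers
    for a in range(L):
        for b in range(a + 1, L):
            d = weight_matrix_dissimilarity(layers[a].weights, layers[b].weights)
            values[a, b] = values[b, a] = d
    return DissimilarityMatrix(values=values, pair_ids=net.pair_ids)


def binarize(layer: Layer) -> Layer:
    """Presence/absence version of a layer: weight 1 where the edge exists."""
    return Layer(
        pair_id=layer.pair_id,
        weights=(layer.weights > 0).astype(float),
        cell_types=layer.cell_types,
        directional=layer.directional,
    )


def write_dissimilarity_csv(dm: DissimilarityMatrix, path: Union[str, Path]) -> None:
    """Square CSV with pair-id header/index at full (repr round-trip) precision."""
    dm.to_frame().to_csv(path, float_format="%.17g")


def read_dissimilarity_csv(path: Union[str, Path]) -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column pair ids differ")
    return DissimilarityMatrix(values=df.to_numpy(dtype=float), pair_ids=tuple(df.columns))
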