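"""Supervised search for a user-specified communication pattern.

The pattern of interest is a binary adjacency matrix over the network's cell
types (1 = edge required, 0 = edge absent).  Every layer is binarized to its
edge support and compared with the query using the same modified-Jaccard
dissimilarity used everywhere else, which on binary matrices is exactly the
Jaccard distance of the two directed edge sets.  The result is the full list
of interacting pairs sorted by increasing dissimilarity to the query, i.e.
best matches first; original edge weights never influence the ranking.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple, Union

import numpy as np
import pandas as pd

from .dissim import binarize, weight_matrix_dissimilarity
from .errors import ConsistencyError, FormatError, ValidationError
from .multiplex import CellTypeSet, MultiplexNetwork

__all__ = [
    "PatternQuery",
    "RankedPairList",
    "search_pattern",
    "read_pattern_csv",
    "read_pattern_edges",
    "write_ranked_tsv",
]


@dataclass(frozen=True, eq=False)
class PatternQuery:
    """A binary N x N adjacency matrix describing the wanted pattern."""

    adjacency: np.ndarray
    cell_types: CellTypeSet

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=float)
        n = len(self.cell_types)
        if adj.shape != (n, n):
            raise ValidationError(
                f"pattern is {adj.shape} but there are {n} cell types"
            )
        if not np.all(np.isin(adj, (0.0, 1.0))):
            raise ValidationError("pattern entries must be 0 or 1")
        if not np.any(adj):
            raise ValidationError("pattern must contain at least one edge")
        object.__setattr__(self, "adjacency", adj)


@dataclass(frozen=True)
class RankedPairList:
    """Interacting pairs with their dissimilarity, in a declared sort order."""

    entries: Tuple[Tuple[str, float], ...]
    order: str  # "ascending" (search) or "descending" (comparison)

    def __post_init__(self):
        if self.order not in ("ascending", "descending"):
            raise ValidationError(f"unknown sort order {self.order!r}")
        ds = [d for _, d in self.entries]
        if any(d < -1e-12 or d > 1 + 1e-12 for d in ds):
            raise ValidationError("dissimilarities must lie in [0, 1]")
        step = np.diff(ds)
        if self.order == "ascending" and np.any(step < 0):
            raise ValidationError("entries are not sorted ascending")
        if self.order == "descending" and np.any(step > 0):
            raise ValidationError("entries are not sorted descending")

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.entries), columns=["pair_id", "dissimilarity"]
        ).assign(rank=lambda df: np.arange(1, len(df) + 1))[
            ["rank", "pair_id", "dissimilarity"]
        ]


def search_pattern(net: MultiplexNetwork, query: PatternQuery) -> RankedPairList:
    """Rank all layers by similarity of their edge support to the query.

    Ties in dissimilarity are broken by lexicographic pair id so the ranking
    is deterministic and independent of layer input order.
    """
    if query.cell_types != net.cell_types:
        raise ConsistencyError("pattern and network index different cell types")
    scored: List[Tuple[str, float]] = []
    for layer in net:
        d = weight_matrix_dissimilarity(binarize(layer).weights, query.adjacency)
        scored.append((layer.pair_id, d))
    scored.sort(key=lambda e: (e[1], e[0]))
    return RankedPairList(entries=tuple(scored), order="ascending")


def read_pattern_csv(path: Union[str, Path], cell_types: CellTypeSet) -> PatternQuery:
    """Binary matrix CSV with cell-type header row and index column."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels differ")
    if list(df.columns) != list(cell_types):
        df = df.reindex(index=list(cell_types), columns=list(cell_types))
        if df.isna().any().any():
            raise ConsistencyError(f"{path}: labels do not match the network's cell types")
    return PatternQuery(adjacency=df.to_numpy(dtype=float), cell_types=cell_types)


def read_pattern_edges(path: Union[str, Path], cell_types: CellTypeSet) -> PatternQuery:
    """Edge-list TSV with columns ``sender`` and ``receiver``."""
    adj = np.zeros((len(cell_types), len(cell_types)))
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"sender", "receiver"}.issubset(reader.fieldnames):
            raise FormatError(f"{path}: expected columns 'sender' and 'receiver'")
        for row in reader:
            try:
                i = cell_types.index(row["sender"])
                j = cell_types.index(row["receiver"])
            except KeyError as exc:
                raise ConsistencyError(f"{path}: {exc}") from exc
            adj[i, j] = 1.0
    return PatternQuery(adjacency=adj, cell_types=cell_types)


def write_ranked_tsv(ranked: RankedPairList, path: Union[str, Path]) -> None:
    ranked.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
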