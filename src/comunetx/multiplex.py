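"""Multiplex-network representation of cell-cell communication.

Each pair of interacting partners (typically a ligand and its receptor) is one
*layer*: a directed weighted graph over a fixed, ordered set of cell types.
The layer is stored as an N x N weight matrix in which ``weights[i, j]`` is the
strength of the communication sent by cell type ``i`` (ligand / partner-1
expresser) and received by cell type ``j`` (receptor / partner-2 expresser).
A weight of exactly zero means the edge is absent; self-edges (autocrine
signalling, ``i == j``) are allowed.  All layers of one multiplex network index
against the same cell-type order, so their adjacency matrices are directly
comparable cell by cell.

The per-node send/receive balance ``delta`` is the weighted out-degree minus
the weighted in-degree: positive for cell types that predominantly send
(produce the ligand), negative for predominant receivers.  Summed over all
nodes of a layer, delta is zero, because every edge credits its sender with
the same weight it debits from its receiver (a self-edge cancels on the spot).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    EmptyLayerError,
    FormatError,
    ShapeError,
    ValidationError,
)

__all__ = [
    "CellTypeSet",
    "Layer",
    "MultiplexNetwork",
    "build_layer",
    "build_multiplex",
    "node_delta",
    "read_layer_csv",
    "write_layer_csv",
    "read_long_tsv",
    "write_long_tsv",
]


@dataclass(frozen=True)
class CellTypeSet:
    """An ordered set of unique cell-type labels shared by all layers.

    The order is fixed for the lifetime of a network; every weight matrix is
    indexed against it (row = sender, column = receiver).
    """

    names: Tuple[str, ...]

    def __init__(self, names: Iterable[str]) -> None:
        names = tuple(str(n) for n in names)
        if len(names) < 2:
            raise ValidationError(f"need at least 2 cell types, got {len(names)}")
        if len(set(names)) != len(names):
            raise ValidationError(f"cell-type labels must be unique: {names}")
        if any(n.strip() == "" for n in names):
            raise ValidationError("cell-type labels must be non-empty")
        object.__setattr__(self, "names", names)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown cell type {name!r}") from None


@dataclass(frozen=True, eq=False)
class Layer:
    """One interacting pair as a directed weighted graph over the cell types.

    ``directional`` distinguishes true ligand->receptor pairs from unordered
    partners (e.g. adhesion molecules), where the arrow merely runs from the
    partner-1 expresser to the partner-2 expresser.  The flag does not change
    any computation; it is carried for provenance and plotting.
    """

    pair_id: str
    weights: np.ndarray
    cell_types: CellTypeSet
    directional: bool = True

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.weights))

    def edge_set(self) -> frozenset:
        """Directed edges (sender index, receiver index) with positive weight."""
        i, j = np.nonzero(self.weights)
        return frozenset(zip(i.tolist(), j.tolist()))

    def to_frame(self) -> pd.DataFrame:
        names = list(self.cell_types)
        return pd.DataFrame(self.weights.copy(), index=names, columns=names)


@dataclass(frozen=True, eq=False)
class MultiplexNetwork:
    """An ordered stack of layers sharing one cell-type set."""

    cell_types: CellTypeSet
    layers: Tuple[Layer, ...]

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)

    @property
    def pair_ids(self) -> Tuple[str, ...]:
        return tuple(layer.pair_id for layer in self.layers)

    def layer(self, pair_id: str) -> Layer:
        for lyr in self.layers:
            if lyr.pair_id == pair_id:
                return lyr
        raise KeyError(f"no layer with pair_id {pair_id!r}")


def build_layer(
    pair_id: str,
    weights: "np.ndarray | Sequence[Sequence[float]]",
    cell_types: CellTypeSet,
    directional: bool = True,
) -> Layer:
    """Validate a weight matrix and wrap it as a :class:`Layer`.

    Parameters
    ----------
    pair_id
        Label of the interacting pair, e.g. ``"Lefty1:Tdgf1"``.
    weights
        Square N x N matrix of non-negative, finite edge weights; row index is
        the sending cell type, column index the receiving one.
    cell_types
        The shared ordered cell-type set the matrix indexes against.
    directional
        True for ligand->receptor pairs, False for unordered partners.

    Raises
    ------
    ShapeError
        Non-square matrix or dimension differing from ``len(cell_types)``.
    ValidationError
        Negative or non-finite entries.
    EmptyLayerError
        All-zero matrix: an edge-less layer has an empty edge set, which would
        make the dissimilarity to another empty layer undefined (0/0), so it
        is rejected at construction.
    """
    w = np.asarray(weights, dtype=float)
    n = len(cell_types)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ShapeError(f"layer {pair_id!r}: weight matrix must be square, got {w.shape}")
    if w.shape[0] != n:
        raise ShapeError(
            f"layer {pair_id!r}: matrix is {w.shape[0]}x{w.shape[1]} but there are {n} cell types"
        )
    if not np.all(np.isfinite(w)):
        raise ValidationError(f"layer {pair_id!r}: weights must be finite")
    if np.any(w < 0):
        raise ValidationError(f"layer {pair_id!r}: weights must be non-negative")
    if not np.any(w > 0):
        raise EmptyLayerError(f"layer {pair_id!r}: all weights are zero")
    pair_id = str(pair_id).strip()
    if not pair_id:
        raise ValidationError("pair_id must be a non-empty string")
    return Layer(pair_id=pair_id, weights=w.copy(), cell_types=cell_types, directional=bool(directional))


def node_delta(layer: Layer) -> Dict[str, float]:
    """Weighted out-degree minus in-degree per cell type.

    Positive values mark predominantly sending cell types, negative values
    predominant receivers; a self-edge adds the same weight to both degrees
    and so contributes nothing.  The values sum to zero (each edge moves
    weight from receiver to sender in this bookkeeping); in floating point the
    per-node values are rounded, so the computed sum is zero to within a few
    ulps rather than bit-exactly.
    """
    out_deg = layer.weights.sum(axis=1)
    in_deg = layer.weights.sum(axis=0)
    delta = out_deg - in_deg
    return {name: float(d) for name, d in zip(layer.cell_types, delta)}


def build_multiplex(layers: Sequence[Layer], cell_types: CellTypeSet) -> MultiplexNetwork:
    """Stack validated layers into a multiplex network, preserving input order.

    Raises
    ------
    ValidationError
        Empty layer list.
    ConsistencyError
        A layer indexed against a different cell-type set, or duplicated
        pair_id.
    """
    layers = tuple(layers)
    if not layers:
        raise ValidationError("a multiplex network needs at least one layer")
    seen = set()
    for lyr in layers:
        if lyr.cell_types != cell_types:
            raise ConsistencyError(
                f"layer {lyr.pair_id!r} indexes cell types {tuple(lyr.cell_types)}, "
                f"expected {tuple(cell_types)}"
            )
        if lyr.pair_id in seen:
            raise ConsistencyError(f"duplicate pair_id {lyr.pair_id!r}")
        seen.add(lyr.pair_id)
    return MultiplexNetwork(cell_types=cell_types, layers=layers)


# ---------------------------------------------------------------------------
# I/O: per-layer CSV matrices and the long-format edge table
# ---------------------------------------------------------------------------

def write_layer_csv(layer: Layer, path: Union[str, Path]) -> None:
    """Write one layer as an N x N CSV with cell-type header row and index column.

    Weights are written with ``repr`` precision so a read-back reproduces the
    exact float values.
    """
    df = layer.to_frame()
    df.to_csv(path, float_format="%.17g")


def read_layer_csv(
    path: Union[str, Path],
    pair_id: str,
    cell_types: "CellTypeSet | None" = None,
    directional: bool = True,
) -> Layer:
    """Read a per-layer CSV matrix written by :func:`write_layer_csv`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels differ")
    cts = cell_types if cell_types is not None else CellTypeSet(df.columns)
    if list(cts) != list(df.columns):
        df = df.reindex(index=list(cts), columns=list(cts))
        if df.isna().any().any():
            raise ConsistencyError(f"{path}: labels do not match the declared cell types")
    return build_layer(pair_id, df.to_numpy(dtype=float), cts, directional=directional)


def write_long_tsv(net: MultiplexNetwork, path: Union[str, Path]) -> None:
    """Write a network as a long-format edge table.

    Columns: ``pair_id, sender, receiver, weight, directional``; one row per
    present (positive-weight) edge.  Cell types with no edge still survive a
    round trip because the header line ``# cell_types:`` records the full
    ordered list.
    """
    names = list(net.cell_types)
    with open(path, "w", newline="") as fh:
        fh.write("# cell_types: " + "\t".join(names) + "\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["pair_id", "sender", "receiver", "weight", "directional"])
        for layer in net:
            i_idx, j_idx = np.nonzero(layer.weights)
            for i, j in zip(i_idx.tolist(), j_idx.tolist()):
                writer.writerow(
                    [layer.pair_id, names[i], names[j],
                     repr(float(layer.weights[i, j])), int(layer.directional)]
                )


def read_long_tsv(path: Union[str, Path]) -> MultiplexNetwork:
    """Read the long-format edge table written by :func:`write_long_tsv`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# cell_types:"):
            raise FormatError(f"{path}: missing '# cell_types:' header line")
        names = first[len("# cell_types:"):].strip().split("\t")
        cts = CellTypeSet(names)
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"pair_id", "sender", "receiver", "weight"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: expected columns {sorted(required)}")
        matrices: Dict[str, np.ndarray] = {}
        directional: Dict[str, bool] = {}
        order: List[str] = []
        for row in reader:
            pid = row["pair_id"]
            if pid not in matrices:
                matrices[pid] = np.zeros((len(cts), len(cts)))
                directional[pid] = bool(int(row.get("directional", 1) or 1))
                order.append(pid)
            try:
                i = cts.index(row["sender"])
                j = cts.index(row["receiver"])
            except KeyError as exc:
                raise ConsistencyError(f"{path}: {exc}") from exc
            w = float(row["weight"])
            if w < 0:
                raise ValidationError(f"{path}: negative weight for {pid}")
            matrices[pid][i, j] = w
    layers = [
        build_layer(pid, matrices[pid], cts, directional=directional[pid]) for pid in order
    ]
    return build_multiplex(layers, cts)
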