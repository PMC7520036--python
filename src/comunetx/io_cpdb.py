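"""Readers for CellPhoneDB-style result tables.

CellPhoneDB (and kin) report, for every ligand-receptor interaction, one
column per *ordered* cell-type pair ``"X|Y"``: partner a is expressed by X,
partner b by Y, and the cell holds the significant mean expression (empty /
NA when the interaction is not significant for that pair of cell types).
Two dialects are supported:

``significant_means``
    One table; a missing value means "not significant", any number present is
    used as the edge weight.

``means + pvalues``
    Two tables with identical layout; a value from the means table is kept as
    a weight only where the matching p-value is at or below a threshold
    (default 0.05).

Direction of the resulting edge follows the receptor flags: if exactly one
partner is a receptor, the arrow runs from the ligand expresser to the
receptor expresser; when neither or both partners are receptors (e.g.
adhesion molecules) the pair is treated as unordered and the arrow runs
partner-1 expresser -> partner-2 expresser, exactly as the columns read.
Interactions significant nowhere produce an empty matrix and are dropped
with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, ValidationError
from .multiplex import CellTypeSet, MultiplexNetwork, build_layer, build_multiplex

__all__ = [
    "InteractionRecord",
    "read_cellphonedb",
    "read_cellphonedb_pvalues",
    "records_to_layers",
]

logger = logging.getLogger(__name__)

_TRUTHY = {"true", "t", "1", "yes"}


@dataclass(frozen=True)
class InteractionRecord:
    """One interaction row: metadata plus per-cell-type-pair weights."""

    pair_id: str
    partner_a: str
    partner_b: str
    receptor_a: bool
    receptor_b: bool
    values: Dict[Tuple[str, str], float] = field(default_factory=dict)

    @property
    def directional(self) -> bool:
        """True when exactly one partner is flagged as the receptor."""
        return self.receptor_a != self.receptor_b


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, float)) and not (isinstance(x, float) and math.isnan(x)):
        return bool(x)
    return str(x).strip().lower() in _TRUTHY


def _split_columns(columns, path) -> Tuple[List[str], List[Tuple[str, str, str]]]:
    """Separate metadata columns from '<X>|<Y>' cell-type-pair columns."""
    meta, pairs = [], []
    seen_pair = False
    for col in columns:
        if "|" in col:
            seen_pair = True
            a, sep, b = col.partition("|")
            if not a or not b or "|" in b:
                raise FormatError(f"{path}: malformed cell-type pair column {col!r}")
            pairs.append((col, a, b))
        else:
            if seen_pair:
                # a metadata-looking column after the pair block is a malformed header
                raise FormatError(
                    f"{path}: column {col!r} after the cell-type pair block lacks a '|'"
                )
            meta.append(col)
    if not pairs:
        raise FormatError(f"{path}: no '<celltype>|<celltype>' columns found")
    return meta, pairs


def _celltypes_from_pairs(pairs) -> CellTypeSet:
    names: List[str] = []
    for _, a, b in pairs:
        for n in (a, b):
            if n not in names:
                names.append(n)
    return CellTypeSet(names)


def read_cellphonedb(
    path: Union[str, Path],
    cell_types: Optional[CellTypeSet] = None,
) -> List[InteractionRecord]:
    """Read a CellPhoneDB v2 ``significant_means`` table.

    The cell-type set is inferred from the pair-column headers unless given
    explicitly; empty cells are non-significant and become weight 0.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta, pairs = _split_columns(list(df.columns), path)
    if "interacting_pair" not in meta:
        raise FormatError(f"{path}: missing 'interacting_pair' column")
    cts = cell_types if cell_types is not None else _celltypes_from_pairs(pairs)
    known = set(cts)
    for col, a, b in pairs:
        if a not in known or b not in known:
            raise ConsistencyError(
                f"{path}: column {col!r} names a cell type outside the declared set"
            )
    records: List[InteractionRecord] = []
    for _, row in df.iterrows():
        values: Dict[Tuple[str, str], float] = {}
        for col, a, b in pairs:
            raw = row[col]
            if pd.isna(raw) or (isinstance(raw, str) and raw.strip() == ""):
                continue
            v = float(raw)
            if v < 0:
                raise ValidationError(
                    f"{path}: negative weight {v} for {row['interacting_pair']!r} in {col!r}"
                )
            if v > 0:
                values[(a, b)] = v
        records.append(
            InteractionRecord(
                pair_id=str(row["interacting_pair"]).strip(),
                partner_a=str(row.get("partner_a", "")),
                partner_b=str(row.get("partner_b", "")),
                receptor_a=_parse_bool(row.get("receptor_a", False)),
                receptor_b=_parse_bool(row.get("receptor_b", False)),
                values=values,
            )
        )
    return records


def read_cellphonedb_pvalues(
    means_path: Union[str, Path],
    pvalues_path: Union[str, Path],
    p_threshold: float = 0.05,
    cell_types: Optional[CellTypeSet] = None,
) -> List[InteractionRecord]:
    """Two-file dialect: keep a mean as weight only where p <= threshold."""
    means = read_cellphonedb(means_path, cell_types=cell_types)
    pv = pd.read_csv(pvalues_path, sep="\t")
    _, pairs = _split_columns(list(pv.columns), pvalues_path)
    if "interacting_pair" not in pv.columns:
        raise FormatError(f"{pvalues_path}: missing 'interacting_pair' column")
    pv = pv.set_index("interacting_pair")
    out: List[InteractionRecord] = []
    for rec in means:
        if rec.pair_id not in pv.index:
            raise ConsistencyError(
                f"{pvalues_path}: no p-value row for {rec.pair_id!r}"
            )
        prow = pv.loc[rec.pair_id]
        kept = {}
        for (a, b), v in rec.values.items():
            p = prow.get(f"{a}|{b}", np.nan)
            if pd.notna(p) and float(p) <= p_threshold:
                kept[(a, b)] = v
        out.append(
            InteractionRecord(
                pair_id=rec.pair_id,
                partner_a=rec.partner_a,
                partner_b=rec.partner_b,
                receptor_a=rec.receptor_a,
                receptor_b=rec.receptor_b,
                values=kept,
            )
        )
    return out


def records_to_layers(
    records: List[InteractionRecord],
    cell_types: Optional[CellTypeSet] = None,
) -> MultiplexNetwork:
    """Turn interaction records into the layers of a multiplex network.

    For a directional pair the value of column ``X|Y`` becomes the edge
    ligand-expresser -> receptor-expresser: ``X -> Y`` when partner b is the
    receptor, ``Y -> X`` when partner a is.  For unordered pairs the edge is
    ``X -> Y`` as the column reads.  All-zero interactions are dropped with a
    logged warning; duplicated pair ids are rejected.
    """
    if not records:
        raise ValidationError("no interaction records to convert")
    if cell_types is None:
        names: List[str] = []
        for rec in records:
            for a, b in rec.values:
                for n in (a, b):
                    if n not in names:
                        names.append(n)
        cts = CellTypeSet(names)
    else:
        cts = cell_types
    layers = []
    for rec in records:
        w = np.zeros((len(cts), len(cts)))
        for (a, b), v in rec.values.items():
            try:
                ia, ib = cts.index(a), cts.index(b)
            except KeyError as exc:
                raise ConsistencyError(f"{rec.pair_id!r}: {exc}") from exc
            if rec.receptor_a and not rec.receptor_b:
                w[ib, ia] = v  # ligand is partner b, expressed by the second cell type
            else:
                w[ia, ib] = v
        if not np.any(w > 0):
            logger.warning("interaction %r significant nowhere; dropped", rec.pair_id)
            continue
        layers.append(build_layer(rec.pair_id, w, cts, directional=rec.directional))
    if not layers:
        raise ValidationError("all interactions were empty; nothing to build")
    return build_multiplex(layers, cts)
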