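"""Figures: communication graphs, dissimilarity heatmap, 2-D layer embedding.

The visual vocabulary is fixed so that patterns are comparable by eye across
figures: cell types sit at deterministic positions on a circle (ordered by
the cell-type set, never force-directed), node colour encodes the
send/receive balance on a diverging red-blue scale centred at zero (red =
net sender, blue = net receiver), edge width grows linearly with weight and
arrowheads point sender -> receiver; autocrine communication is drawn as a
self-loop.  Rendering never mutates its inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import scipy.cluster.hierarchy as sch
import seaborn as sns

from .cluster import AveragePattern, ClusterAssignment
from .dissim import DissimilarityMatrix
from .multiplex import CellTypeSet, Layer, node_delta

__all__ = ["GraphFigureSpec", "plot_layer", "plot_heatmap", "plot_embedding"]


@dataclass(frozen=True)
class GraphFigureSpec:
    """Styling knobs for communication-graph figures.

    ``delta_limit`` fixes the colour-scale bound (+- that value); when None,
    each figure uses its own max |balance|, so colours are comparable within
    one figure only.  Pass the max over a whole figure set to make a report
    internally comparable.
    """

    node_size: float = 1600.0
    max_edge_width: float = 6.0
    delta_limit: Optional[float] = None
    cmap: str = "RdBu_r"


def _circular_positions(cell_types: CellTypeSet) -> dict:
    n = len(cell_types)
    return {
        name: (math.cos(2 * math.pi * k / n - math.pi / 2),
               -math.sin(2 * math.pi * k / n - math.pi / 2))
        for k, name in enumerate(cell_types)
    }


def plot_layer(
    obj: Union[Layer, AveragePattern],
    out_path: Union[str, Path],
    cell_types: Optional[CellTypeSet] = None,
    spec: GraphFigureSpec = GraphFigureSpec(),
    title: Optional[str] = None,
) -> Path:
    """Draw one layer (or a cluster's average pattern) as a directed graph.

    ``cell_types`` is required for an :class:`AveragePattern` (which does not
    carry them); a :class:`Layer` brings its own.
    """
    if isinstance(obj, Layer):
        weights, cts = obj.weights, obj.cell_types
        delta = node_delta(obj)
        label = title if title is not None else obj.pair_id
    else:
        if cell_types is None:
            raise ValueError("cell_types is required to plot an AveragePattern")
        weights, cts = obj.mean_weights, cell_types
        delta = obj.mean_delta
        label = title if title is not None else f"cluster {obj.cluster_label} average pattern"
    names = list(cts)
    pos = _circular_positions(cts)
    g = nx.DiGraph()
    g.add_nodes_from(names)
    wmax = float(weights.max())
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if weights[i, j] > 0:
                g.add_edge(a, b, weight=float(weights[i, j]))
    dmax = spec.delta_limit
    if dmax is None:
        dmax = max(abs(v) for v in delta.values()) or 1.0
    fig, ax = plt.subplots(figsize=(5, 5))
    nx.draw_networkx_nodes(
        g, pos, ax=ax,
        node_color=[delta[n] for n in names],
        cmap=plt.get_cmap(spec.cmap), vmin=-dmax, vmax=dmax,
        node_size=spec.node_size, edgecolors="black",
    )
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=9)
    widths = [spec.max_edge_width * g.edges[e]["weight"] / wmax for e in g.edges]
    nx.draw_networkx_edges(
        g, pos, ax=ax, width=widths, arrows=True, arrowsize=14,
        connectionstyle="arc3,rad=0.08", node_size=spec.node_size,
    )
    ax.set_title(label)
    ax.set_axis_off()
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    out_path = Path(out_path)
    fig.savefig(out_path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return out_path


def plot_heatmap(
    dm: DissimilarityMatrix,
    out_path: Union[str, Path],
    assignment: Optional[ClusterAssignment] = None,
    linkage: Optional[np.ndarray] = None,
    cmap: str = "viridis",
) -> Path:
    """Heatmap of the dissimilarity matrix, rows in dendrogram leaf order.

    The ordering linkage is taken from ``linkage``, from the assignment's
    stored linkage, or (when neither is given) the file order of the matrix.
    """
    order = np.arange(len(dm))
    Z = linkage if linkage is not None else (assignment.linkage if assignment else None)
    if Z is not None:
        order = np.asarray(sch.leaves_list(Z))
    ids = [dm.pair_ids[i] for i in order]
    values = dm.values[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(dm)), max(3.5, 0.3 * len(dm))))
    sns.heatmap(
        values, ax=ax, cmap=cmap, vmin=0.0, vmax=1.0, square=True,
        xticklabels=ids, yticklabels=ids,
        cbar_kws={"label": "dissimilarity"},
    )
    ax.tick_params(labelsize=6)
    out_path = Path(out_path)
    fig.savefig(out_path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return out_path


def plot_embedding(
    coords: np.ndarray,
    out_path: Union[str, Path],
    assignment: Optional[ClusterAssignment] = None,
    pair_ids: Optional[list] = None,
    title: str = "layer embedding",
) -> Path:
    """Scatter of a 2-D layer embedding, coloured by cluster when available."""
    coords = np.asarray(coords, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    if assignment is not None and pair_ids is not None:
        labels = np.array([assignment.labels[p] for p in pair_ids])
        for lab in np.unique(labels):
            mask = labels == lab
            name = "unassigned" if lab == 0 else f"cluster {lab}"
            ax.scatter(coords[mask, 0], coords[mask, 1], s=28, label=name,
                       color="grey" if lab == 0 else None)
        ax.legend(fontsize=7, loc="best")
    else:
        ax.scatter(coords[:, 0], coords[:, 1], s=28)
    ax.set_title(title)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    out_path = Path(out_path)
    fig.savefig(out_path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return out_path
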