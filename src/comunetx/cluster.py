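"""Unsupervised clustering of communication patterns.

Layers (interacting pairs) with similar communication patterns are grouped by
average-linkage (UPGMA) hierarchical clustering of the dissimilarity matrix,
followed by the adaptive Dynamic Hybrid tree cut (default ``deep_split=0``,
``min_cluster_size=6``).  Each resulting cluster is summarised by an *average
pattern*: the arithmetic mean of the member weight matrices together with the
mean per-node send/receive balance.  Because the balance is linear in the
weights, the mean balance equals the balance of the mean matrix.

The clusterer is exposed as a scikit-learn-compatible estimator,
:class:`HybridTreeCut`, that fits on a precomputed square dissimilarity
matrix (the same calling convention as ``AgglomerativeClustering`` with
``metric="precomputed"``); :func:`hybrid_tree_cut` is a thin wrapper mapping
the result back onto pair ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.cluster.hierarchy as sch
from sklearn.base import BaseEstimator, ClusterMixin

from ._treecut import cutree_hybrid
from .dissim import DissimilarityMatrix
from .errors import ValidationError
from .multiplex import Layer, MultiplexNetwork, node_delta

__all__ = [
    "ClusterAssignment",
    "AveragePattern",
    "HybridTreeCut",
    "hierarchical_linkage",
    "hybrid_tree_cut",
    "average_pattern",
    "embed_layers",
]


def hierarchical_linkage(dm: DissimilarityMatrix, method: str = "average") -> np.ndarray:
    """Scipy linkage matrix of the layers, default UPGMA (average linkage).

    Merge heights are non-decreasing for average linkage on a proper
    dissimilarity; when two merge candidates tie, the pair with the lowest
    indices merges first (scipy's deterministic order), so results are stable
    across runs.
    """
    if len(dm) < 2:
        raise ValidationError("need at least 2 layers to build a linkage")
    return sch.linkage(dm.condensed(), method=method)


class HybridTreeCut(ClusterMixin, BaseEstimator):
    """Average-linkage clustering with the Dynamic Hybrid tree cut.

    Parameters
    ----------
    deep_split : int, default 0
        Split sensitivity in {0..4}; 0 = most conservative (fewest clusters).
    min_cluster_size : int, default 6
        Minimum cluster size; smaller branches stay unassigned (label 0).
    linkage_method : str, default "average"
        Agglomeration method handed to scipy.
    cut_height : float or None
        Ceiling merge height; defaults to 99% of the top merge.
    pam_stage : bool, default True
        Assign leftover objects to the nearest cluster afterwards.

    Attributes
    ----------
    labels_ : ndarray of shape (L,)
        Cluster label per object; 0 means unassigned.
    n_clusters_ : int
        Number of labels >= 1.
    linkage_ : ndarray of shape (L-1, 4)
        The fitted scipy linkage matrix.

    Examples
    --------
    >>> import numpy as np
    >>> D = np.array([[0, .1, .9], [.1, 0, .9], [.9, .9, 0]])
    >>> HybridTreeCut(min_cluster_size=2).fit_predict(D)
    array([...])
    """

    def __init__(
        self,
        deep_split: int = 0,
        min_cluster_size: int = 6,
        linkage_method: str = "average",
        cut_height: Optional[float] = None,
        pam_stage: bool = True,
    ):
        self.deep_split = deep_split
        self.min_cluster_size = min_cluster_size
        self.linkage_method = linkage_method
        self.cut_height = cut_height
        self.pam_stage = pam_stage

    def fit(self, X, y=None):
        """Fit on a precomputed square dissimilarity matrix X (L x L)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValidationError(f"X must be a square dissimilarity matrix, got {X.shape}")
        if not np.allclose(X, X.T, atol=1e-12):
            raise ValidationError("X must be symmetric")
        if np.any(X < 0):
            raise ValidationError("dissimilarities must be non-negative")
        dm = DissimilarityMatrix(
            values=(X + X.T) / 2.0 * (1 - np.eye(len(X))),
            pair_ids=tuple(str(i) for i in range(len(X))),
        )
        self.linkage_ = hierarchical_linkage(dm, method=self.linkage_method)
        self.labels_ = cutree_hybrid(
            self.linkage_,
            dm.values,
            deep_split=self.deep_split,
            min_cluster_size=self.min_cluster_size,
            cut_height=self.cut_height,
            pam_stage=self.pam_stage,
        )
        self.n_clusters_ = int(self.labels_.max(initial=0))
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass(frozen=True, eq=False)
class ClusterAssignment:
    """Cluster labels per pair id plus the linkage they came from.

    ``labels`` maps every pair id of the clustered network to an integer
    label; labels >= 1 are clusters of at least ``min_cluster_size`` members,
    0 marks unassigned layers (reported, never silently dropped).
    """

    labels: Dict[str, int]
    linkage: np.ndarray
    n_clusters: int

    def members(self, cluster_label: int) -> Tuple[str, ...]:
        return tuple(pid for pid, lab in self.labels.items() if lab == cluster_label)

    @property
    def unassigned(self) -> Tuple[str, ...]:
        return self.members(0)


def hybrid_tree_cut(
    linkage: np.ndarray,
    dm: DissimilarityMatrix,
    deep_split: int = 0,
    min_cluster_size: int = 6,
    pam_stage: bool = True,
    cut_height: Optional[float] = None,
) -> ClusterAssignment:
    """Dynamic Hybrid cut of a fitted linkage, keyed by pair id."""
    labels = cutree_hybrid(
        np.asarray(linkage, dtype=float),
        dm.values,
        deep_split=deep_split,
        min_cluster_size=min_cluster_size,
        cut_height=cut_height,
        pam_stage=pam_stage,
    )
    mapping = {pid: int(lab) for pid, lab in zip(dm.pair_ids, labels)}
    return ClusterAssignment(
        labels=mapping, linkage=np.asarray(linkage, dtype=float),
        n_clusters=int(labels.max(initial=0)),
    )


@dataclass(frozen=True, eq=False)
class AveragePattern:
    """Mean communication pattern of one cluster."""

    cluster_label: int
    mean_weights: np.ndarray
    mean_delta: Dict[str, float]
    member_ids: Tuple[str, ...]


def average_pattern(
    net: MultiplexNetwork, assignment: ClusterAssignment, cluster_label: int
) -> AveragePattern:
    """Arithmetic mean of the member weight matrices and node balances.

    Raises
    ------
    KeyError
        ``cluster_label`` has no members in the assignment.
    """
    members = assignment.members(cluster_label)
    if not members:
        raise KeyError(f"cluster label {cluster_label} has no members")
    mats = [net.layer(pid).weights for pid in members]
    mean_w = np.mean(mats, axis=0)
    deltas = [node_delta(net.layer(pid)) for pid in members]
    mean_delta = {
        ct: float(np.mean([d[ct] for d in deltas])) for ct in net.cell_types
    }
    return AveragePattern(
        cluster_label=int(cluster_label),
        mean_weights=mean_w,
        mean_delta=mean_delta,
        member_ids=members,
    )


def mean_pattern_layer(pattern: AveragePattern, net: MultiplexNetwork) -> Layer:
    """The average pattern wrapped as a (non-validated-empty) plotting layer."""
    return Layer(
        pair_id=f"cluster {pattern.cluster_label}",
        weights=pattern.mean_weights,
        cell_types=net.cell_types,
        directional=True,
    )


def embed_layers(
    dm: DissimilarityMatrix, seed: int, method: str = "auto"
) -> Tuple[np.ndarray, str]:
    """2-D embedding of the layers from the precomputed dissimilarity matrix.

    ``method`` is "umap", "mds" or "auto" (UMAP when importable, otherwise
    classical metric MDS).  Returns the (L, 2) coordinates and the method
    actually used; deterministic for a fixed seed.
    """
    L = len(dm)
    if L < 4:
        raise ValidationError(f"need at least 4 layers to embed, got {L}")
    if method not in ("auto", "umap", "mds"):
        raise ValidationError(f"unknown embedding method {method!r}")
    use = method
    if method == "auto":
        try:
            import umap  # noqa: F401
            use = "umap"
        except ImportError:
            use = "mds"
    if use == "umap":
        import umap

        reducer = umap.UMAP(
            n_components=2,
            metric="precomputed",
            n_neighbors=min(15, L - 1),
            random_state=int(seed),
            n_jobs=1,
        )
        coords = reducer.fit_transform(dm.values)
    else:
        import inspect

        from sklearn.manifold import MDS

        kwargs = dict(n_components=2, random_state=int(seed), normalized_stress="auto")
        sig = inspect.signature(MDS.__init__).parameters
        if "dissimilarity" in sig and sig["dissimilarity"].default != "deprecated":
            kwargs["dissimilarity"] = "precomputed"
        else:
            kwargs["metric"] = "precomputed"
        if "init" in sig:
            kwargs["init"] = "random"
        coords = MDS(**kwargs).fit_transform(dm.values)
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("embedding produced non-finite coordinates")
    return coords, use
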