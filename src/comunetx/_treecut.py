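"""Dynamic Hybrid adaptive dendrogram cutting.

Hierarchical clustering of a layer dissimilarity matrix yields a merge tree;
a single horizontal cut through it is a poor way to define clusters when the
tree mixes tight and loose groups.  The Dynamic Hybrid procedure instead
walks the merge tree bottom-up and declares a branch a cluster when it

1. contains at least ``min_cluster_size`` objects,
2. is internally tight: the mean dissimilarity among its *core* (the
   earliest-attaching objects) stays below a scatter ceiling, and
3. is separated from its surroundings: the height at which the branch attaches
   to the rest of the tree exceeds the core scatter by a minimum *gap*.

``deep_split`` in {0..4} tunes how aggressively branches are split: 0 is the
most conservative setting (large scatter ceiling margin and gap requirement,
hence fewer, broader clusters), 4 the most sensitive.  The scatter ceiling and
gap are expressed relative to the dendrogram's height range between a low
reference height (5th percentile of merge heights) and the cut height
(by default 99% of the top merge): with ``q = deep_split / 4``,

    max_core_scatter = 0.64 + 0.31 * q            (relative)
    min_gap          = (1 - max_core_scatter) * 3/4

Objects on branches that never qualify keep label 0 (unassigned).  An
optional PAM-like stage then assigns each unlabelled object to the cluster
with the smallest average dissimilarity, provided that average is below the
cut height.  Clusters are numbered 1..K by decreasing size (ties broken by
smallest member index), matching the convention that label 1 is the largest
cluster and 0 means noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .errors import ValidationError

__all__ = ["cutree_hybrid", "TreeCutParams"]


@dataclass(frozen=True)
class TreeCutParams:
    """Derived absolute thresholds actually used by a tree-cut run."""

    cut_height: float
    ref_height: float
    max_abs_core_scatter: float
    min_abs_gap: float


def _derive_params(
    heights: np.ndarray, deep_split: int, cut_height: Optional[float]
) -> TreeCutParams:
    max_h = float(np.max(heights))
    if cut_height is None:
        cut_height = 0.99 * max_h
    ref_height = float(min(np.quantile(heights, 0.05), cut_height))
    q = deep_split / 4.0
    max_core_scatter = 0.64 + 0.31 * q
    min_gap = (1.0 - max_core_scatter) * 0.75
    span = cut_height - ref_height
    return TreeCutParams(
        cut_height=float(cut_height),
        ref_height=ref_height,
        max_abs_core_scatter=ref_height + max_core_scatter * span,
        min_abs_gap=min_gap * span,
    )


def _core_size(branch_size: int, min_cluster_size: int) -> int:
    """Number of earliest-attaching objects that form a branch's core.

    Slightly more than half the minimum cluster size, growing with the square
    root of the branch size, so the core stays a small, tight kernel even for
    big branches.
    """
    base = min_cluster_size // 2 + 1
    if base < branch_size:
        return int(base + math.sqrt(branch_size - base))
    return branch_size


class _Branch:
    """A growing branch: member leaves with the heights at which they joined."""

    __slots__ = ("members", "join_heights")

    def __init__(self, members: List[int], join_heights: List[float]):
        self.members = members
        self.join_heights = join_heights

    def absorb(self, other: "_Branch") -> None:
        self.members += other.members
        self.join_heights += other.join_heights

    def core(self, min_cluster_size: int) -> List[int]:
        n_core = _core_size(len(self.members), min_cluster_size)
        order = sorted(range(len(self.members)), key=lambda k: (self.join_heights[k], k))
        return [self.members[k] for k in order[:n_core]]


_COMPOSITE = "composite"  # node already containing committed clusters


def cutree_hybrid(
    linkage: np.ndarray,
    dist: np.ndarray,
    deep_split: int = 0,
    min_cluster_size: int = 6,
    cut_height: Optional[float] = None,
    pam_stage: bool = True,
) -> np.ndarray:
    """Cluster labels for the leaves of a hierarchical merge tree.

    Parameters
    ----------
    linkage
        Scipy linkage matrix ((L-1) x 4) built from ``dist``; merge heights
        must be non-decreasing (guaranteed for average linkage on a proper
        dissimilarity).
    dist
        Square L x L dissimilarity matrix the tree was built from.
    deep_split
        Split sensitivity in {0, 1, 2, 3, 4}; 0 = most conservative.
    min_cluster_size
        Minimum number of objects for a branch to become a cluster.
    cut_height
        Merges at or above this height are never followed; default 99% of the
        top merge height.
    pam_stage
        Assign leftover objects to the nearest cluster (average dissimilarity,
        capped at the cut height) after branch evaluation.

    Returns
    -------
    numpy.ndarray of int
        One label per leaf, in the leaf order of ``dist``; 0 = unassigned.
    """
    if not (isinstance(deep_split, (int, np.integer)) and 0 <= deep_split <= 4):
        raise ValidationError(f"deep_split must be an integer in 0..4, got {deep_split!r}")
    if not (isinstance(min_cluster_size, (int, np.integer)) and min_cluster_size >= 1):
        raise ValidationError(f"min_cluster_size must be >= 1, got {min_cluster_size!r}")
    dist = np.asarray(dist, dtype=float)
    L = dist.shape[0]
    if linkage.shape != (L - 1, 4):
        raise ValidationError(
            f"linkage shape {linkage.shape} does not match {L} leaves"
        )
    heights = linkage[:, 2]
    if np.any(np.diff(heights) < -1e-12):
        raise ValidationError("merge heights must be non-decreasing")
    params = _derive_params(heights, int(deep_split), cut_height)

    def qualifies(branch: _Branch, attach_height: float) -> bool:
        if len(branch.members) < min_cluster_size:
            return False
        core = branch.core(min_cluster_size)
        if len(core) > 1:
            sub = dist[np.ix_(core, core)]
            scatter = float(sub.sum() / (len(core) * (len(core) - 1)))
        else:
            scatter = 0.0
        if scatter > params.max_abs_core_scatter:
            return False
        return (attach_height - scatter) >= params.min_abs_gap

    committed: List[List[int]] = []
    # node id -> leaf index (int), _Branch, or _COMPOSITE
    nodes: dict = {i: i for i in range(L)}

    for k in range(L - 1):
        a, b, h = int(linkage[k, 0]), int(linkage[k, 1]), float(linkage[k, 2])
        left, right = nodes.pop(a), nodes.pop(b)
        if h >= params.cut_height:
            # cut here: finalize each side independently
            for side in (left, right):
                if isinstance(side, _Branch) and qualifies(side, params.cut_height):
                    committed.append(side.members)
            nodes[L + k] = _COMPOSITE
            continue
        left_is_branch = isinstance(left, _Branch)
        right_is_branch = isinstance(right, _Branch)
        if left is _COMPOSITE or right is _COMPOSITE:
            other = right if left is _COMPOSITE else left
            if isinstance(other, _Branch) and qualifies(other, h):
                committed.append(other.members)
            nodes[L + k] = _COMPOSITE
        elif left_is_branch and right_is_branch:
            lq, rq = qualifies(left, h), qualifies(right, h)
            if lq and rq:
                committed.append(left.members)
                committed.append(right.members)
                nodes[L + k] = _COMPOSITE
            elif lq:
                left.absorb(right)
                nodes[L + k] = left
            elif rq:
                right.absorb(left)
                nodes[L + k] = right
            else:
                left.absorb(right)
                nodes[L + k] = left
        elif left_is_branch or right_is_branch:
            branch = left if left_is_branch else right
            leaf = right if left_is_branch else left
            branch.members.append(leaf)
            branch.join_heights.append(h)
            nodes[L + k] = branch
        else:  # two singletons
            nodes[L + k] = _Branch([left, right], [h, h])

    for node in nodes.values():
        if isinstance(node, _Branch) and qualifies(node, params.cut_height):
            committed.append(node.members)

    committed.sort(key=lambda mem: (-len(mem), min(mem)))
    labels = np.zeros(L, dtype=int)
    for lab, members in enumerate(committed, start=1):
        labels[members] = lab

    if pam_stage and committed:
        targets = [np.asarray(mem) for mem in committed]
        for leaf in np.flatnonzero(labels == 0):
            avg = np.array([dist[leaf, t].mean() for t in targets])
            best = int(np.argmin(avg))
            if avg[best] < params.cut_height:
                labels[leaf] = best + 1
    return labels
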