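"""Synthetic multiplex communication networks with planted structure.

The generator emulates the shape of real cell-cell communication output: a
stack of sparse directed weight matrices over a handful of cell types, where
groups of interacting pairs share a communication *archetype* (the situation
the clustering step is designed to recover).  Each archetype is a binary
adjacency matrix; every member layer starts from it, flips each cell
independently with probability ``edge_flip_prob`` (present -> absent and
absent -> present at the same rate, keeping expected density stable), and
draws the weights of the surviving edges from a lognormal law, mimicking the
positive, right-skewed mean-expression scores produced by upstream tools.
With ``sigma = 0`` and ``edge_flip_prob = 0`` all members of an archetype are
identical, giving exact within-archetype dissimilarity 0.

``perturb_network`` rewires a chosen fraction of the edges of named layers to
uniformly drawn absent cells, which drives the differential-comparison tests:
the more a layer is rewired, the larger its dissimilarity across the two
"conditions".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .multiplex import (
    CellTypeSet,
    Layer,
    MultiplexNetwork,
    build_layer,
    build_multiplex,
)

__all__ = ["ArchetypeSpec", "random_archetypes", "generate_network", "perturb_network"]


@dataclass(frozen=True, eq=False)
class ArchetypeSpec:
    """Recipe for a planted multiplex network.

    Parameters
    ----------
    n_celltypes
        Number of cell types N (nodes of every layer).
    archetypes
        Pairwise-distinct binary N x N matrices, each with at least one edge.
    members_per_archetype
        Number of layers generated per archetype.
    weight_mu, weight_sigma
        Parameters of the lognormal edge-weight law (of log-weight mean and
        standard deviation); defaults 0 and 0.5 give weights centred near 1
        with the mild right skew typical of mean-expression scores.
    edge_flip_prob
        Per-cell independent flip probability, in [0, 0.5); 0 plants exact
        copies of the archetype support.
    seed
        Seed of the generator's private random state.
    """

    n_celltypes: int
    archetypes: Sequence[np.ndarray]
    members_per_archetype: int = 6
    weight_mu: float = 0.0
    weight_sigma: float = 0.5
    edge_flip_prob: float = 0.1
    seed: int = 0

    def __post_init__(self):
        n = self.n_celltypes
        if n < 2:
            raise ValidationError("need at least 2 cell types")
        if self.members_per_archetype < 1:
            raise ValidationError("members_per_archetype must be >= 1")
        if not (0 <= self.edge_flip_prob < 0.5):
            raise ValidationError("edge_flip_prob must lie in [0, 0.5)")
        if self.weight_sigma < 0:
            raise ValidationError("weight_sigma must be >= 0")
        if not self.archetypes:
            raise ValidationError("need at least one archetype")
        mats = []
        for k, a in enumerate(self.archetypes):
            a = np.asarray(a, dtype=float)
            if a.shape != (n, n):
                raise ValidationError(f"archetype {k} has shape {a.shape}, expected ({n}, {n})")
            if not np.all(np.isin(a, (0.0, 1.0))):
                raise ValidationError(f"archetype {k} must be binary")
            if not np.any(a):
                raise ValidationError(f"archetype {k} has no edge")
            mats.append(a)
        for i in range(len(mats)):
            for j in range(i + 1, len(mats)):
                if np.array_equal(mats[i], mats[j]):
                    raise ValidationError(f"archetypes {i} and {j} are identical")
        object.__setattr__(self, "archetypes", tuple(mats))


def random_archetypes(
    n_celltypes: int,
    n_archetypes: int,
    density: float = 0.3,
    seed: int = 0,
    disjoint: bool = False,
) -> List[np.ndarray]:
    """Draw distinct random binary archetype matrices.

    With ``disjoint=True`` the archetypes use non-overlapping sets of cells
    of the N x N grid, so any two layers built from different archetypes have
    dissimilarity exactly 1 (useful for noiseless separability fixtures).
    """
    rng = np.random.default_rng(seed)
    n2 = n_celltypes * n_celltypes
    n_edges = max(1, int(round(density * n2)))
    if disjoint:
        if n_archetypes * n_edges > n2:
            raise ValidationError("too many archetypes/edges for disjoint supports")
        cells = rng.permutation(n2)
        out = []
        for k in range(n_archetypes):
            a = np.zeros(n2)
            a[cells[k * n_edges:(k + 1) * n_edges]] = 1.0
            out.append(a.reshape(n_celltypes, n_celltypes))
        return out
    out = []
    attempts = 0
    while len(out) < n_archetypes:
        attempts += 1
        if attempts > 1000 * n_archetypes:
            raise ValidationError("could not draw distinct archetypes; lower the count")
        a = np.zeros(n2)
        a[rng.choice(n2, size=n_edges, replace=False)] = 1.0
        a = a.reshape(n_celltypes, n_celltypes)
        if all(not np.array_equal(a, b) for b in out):
            out.append(a)
    return out


def generate_network(spec: ArchetypeSpec) -> Tuple[MultiplexNetwork, Dict[str, int]]:
    """Generate the planted network and its ground-truth archetype labels.

    Returns the network plus a map pair_id -> archetype index (1-based, so it
    compares directly with cluster labels where 0 means unassigned).  Output
    is a pure function of the spec, including the seed.  A member whose flips
    would leave it edge-less is redrawn (an empty layer is not a valid layer);
    with ``edge_flip_prob < 0.5`` and at least one archetype edge this is
    rare and does not bias the flip rate noticeably.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"CT{i + 1}" for i in range(spec.n_celltypes)]
    cts = CellTypeSet(names)
    layers: List[Layer] = []
    truth: Dict[str, int] = {}
    for k, arch in enumerate(spec.archetypes, start=1):
        for m in range(spec.members_per_archetype):
            pair_id = f"L{k}.{m + 1}:R{k}.{m + 1}"
            for _ in range(1000):
                flips = rng.random(arch.shape) < spec.edge_flip_prob
                support = np.logical_xor(arch > 0, flips)
                if support.any():
                    break
            else:
                raise ValidationError("could not generate a non-empty member layer")
            weights = np.where(
                support,
                np.exp(rng.normal(spec.weight_mu, spec.weight_sigma, arch.shape)),
                0.0,
            )
            layers.append(build_layer(pair_id, weights, cts, directional=True))
            truth[pair_id] = k
    return build_multiplex(layers, cts), truth


def perturb_network(
    net: MultiplexNetwork,
    pair_ids: Sequence[str],
    rewire_frac: float,
    seed: int = 0,
) -> MultiplexNetwork:
    """Rewire a fraction of the edges of the named layers; copy the rest.

    For each named layer, ``round(rewire_frac * n_edges)`` edges (chosen
    uniformly without replacement) are moved, one by one, to a uniformly
    chosen cell that is empty both now and in the original layer, keeping
    their weights.  Excluding vacated cells as targets means a fully rewired
    layer (``rewire_frac = 1``) has an edge set disjoint from the original,
    hence dissimilarity exactly 1 to it; this needs the layer to occupy at
    most half of the N x N cells.

    Raises
    ------
    KeyError
        A pair id not present in the network.
    ValidationError
        ``rewire_frac`` outside [0, 1], or no absent cell left to move an
        edge to.
    """
    if not (0 <= rewire_frac <= 1):
        raise ValidationError("rewire_frac must lie in [0, 1]")
    targets = set(pair_ids)
    for pid in targets:
        net.layer(pid)  # raises KeyError for unknown ids
    rng = np.random.default_rng(seed)
    new_layers: List[Layer] = []
    for layer in net:
        if layer.pair_id not in targets:
            new_layers.append(layer)
            continue
        w = layer.weights.copy()
        original_support = w > 0
        edges = np.argwhere(original_support)
        n_move = int(round(rewire_frac * len(edges)))
        move_idx = rng.choice(len(edges), size=n_move, replace=False)
        for ei in move_idx:
            i, j = edges[ei]
            absent = np.argwhere((w == 0) & ~original_support)
            if len(absent) == 0:
                raise ValidationError(
                    f"layer {layer.pair_id!r} is fully connected; cannot rewire"
                )
            ti, tj = absent[rng.integers(len(absent))]
            w[ti, tj] = w[i, j]
            w[i, j] = 0.0
        new_layers.append(
            build_layer(layer.pair_id, w, net.cell_types, directional=layer.directional)
        )
    return build_multiplex(new_layers, net.cell_types)
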