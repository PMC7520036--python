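import numpy as np
import pytest

from comunetx import (
    ArchetypeSpec,
    CellTypeSet,
    build_layer,
    build_multiplex,
    generate_network,
    random_archetypes,
)


@pytest.fixture
def cts_abc():
    return CellTypeSet(["A", "B", "C"])


def make_layer(pair_id, edges, cts, directional=True):
    """Layer from an edge dict {(sender_label, receiver_label): weight}."""
    w = np.zeros((len(cts), len(cts)))
    for (a, b), v in edges.items():
        w[cts.index(a), cts.index(b)] = v
    return build_layer(pair_id, w, cts, directional=directional)


def random_layer(rng, cts, density=0.4, pair_id="p"):
    """A random valid layer: lognormal weights on a random support."""
    n = len(cts)
    while True:
        support = rng.random((n, n)) < density
        if support.any():
            break
    w = np.where(support, np.exp(rng.normal(0, 0.5, (n, n))), 0.0)
    return build_layer(pair_id, w, cts, directional=True)


def random_network(rng, n_celltypes=4, n_layers=5, density=0.4):
    cts = CellTypeSet([f"CT{i}" for i in range(n_celltypes)])
    layers = [
        random_layer(rng, cts, density=density, pair_id=f"pair{k}")
        for k in range(n_layers)
    ]
    return build_multiplex(layers, cts)


@pytest.fixture
def noiseless_two_archetypes():
    """Two disjoint archetypes, six exact copies each: within d=0, between d=1."""
    spec = ArchetypeSpec(
        n_celltypes=5,
        archetypes=random_archetypes(5, 2, density=0.2, seed=3, disjoint=True),
        members_per_archetype=6,
        weight_sigma=0.0,
        edge_flip_prob=0.0,
        seed=11,
    )
    return generate_network(spec)


@pytest.fixture
def noisy_network():
    """Three archetypes, 10% edge flips, lognormal weights."""
    spec = ArchetypeSpec(
        n_celltypes=6,
        archetypes=random_archetypes(6, 3, density=0.3, seed=21),
        members_per_archetype=7,
        edge_flip_prob=0.1,
        seed=22,
    )
    return generate_network(spec)
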