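"""Linkage against a hand-rolled UPGMA oracle, tree cut, average patterns."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from comunetx import (
    ArchetypeSpec,
    DissimilarityMatrix,
    HybridTreeCut,
    ValidationError,
    average_pattern,
    build_multiplex,
    embed_layers,
    generate_network,
    hierarchical_linkage,
    hybrid_tree_cut,
    node_delta,
    pairwise_dissimilarity,
    random_archetypes,
)

from .conftest import make_layer, random_network


def upgma_oracle(d):
    """O(L^3) UPGMA producing the cophenetic matrix and sorted merge heights.

    Clusters merge at the smallest average inter-cluster dissimilarity; the
    average is the size-weighted (arithmetic over member pairs) mean.  Ties
    break on the lowest cluster indices.
    """
    d = np.asarray(d, dtype=float)
    L = d.shape[0]
    clusters = [[i] for i in range(L)]
    coph = np.zeros((L, L))
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                avg = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or avg < best[0] - 1e-15:
                    best = (avg, a, b)
        h, a, b = best
        heights.append(h)
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(sorted(heights)), coph


def random_dissimilarity(rng, L):
    v = rng.random((L, L))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return DissimilarityMatrix(values=v, pair_ids=tuple(f"p{i}" for i in range(L)))


class TestLinkage:
    def test_two_leaf_tree(self):
        dm = DissimilarityMatrix(values=np.array([[0, 0.4], [0.4, 0]]), pair_ids=("a", "b"))
        Z = hierarchical_linkage(dm)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.4)

    def test_three_leaf_average_of_equal_distances(self):
        v = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        dm = DissimilarityMatrix(values=v, pair_ids=("a", "b", "c"))
        Z = hierarchical_linkage(dm)
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.9)  # average of two equal distances

    def test_matches_upgma_oracle(self):
        import scipy.cluster.hierarchy as sch

        rng = np.random.default_rng(2024)
        for trial in range(25):
            L = int(rng.integers(3, 11))
            dm = random_dissimilarity(rng, L)
            Z = hierarchical_linkage(dm)
            exp_heights, exp_coph = upgma_oracle(dm.values)
            assert np.allclose(np.sort(Z[:, 2]), exp_heights, atol=1e-10)
            got_coph = sch.cophenet(Z)
            from scipy.spatial.distance import squareform

            assert np.allclose(squareform(got_coph), exp_coph, atol=1e-10)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(5)
        Z = hierarchical_linkage(random_dissimilarity(rng, 9))
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)


class TestHybridTreeCut:
    def test_recovers_two_planted_archetypes(self, noiseless_two_archetypes):
        net, truth = noiseless_two_archetypes
        dm = pairwise_dissimilarity(net)
        asg = hybrid_tree_cut(hierarchical_linkage(dm), dm)
        assert asg.n_clusters == 2
        pred = [asg.labels[p] for p in net.pair_ids]
        gt = [truth[p] for p in net.pair_ids]
        assert adjusted_rand_score(gt, pred) == 1.0

    def test_instance_smaller_than_min_cluster_size_all_unassigned(self):
        # documented reference behaviour: nothing can satisfy the minimum
        # cluster size, so every object keeps label 0
        rng = np.random.default_rng(1)
        dm = pairwise_dissimilarity(random_network(rng, n_layers=4))
        asg = hybrid_tree_cut(hierarchical_linkage(dm), dm, min_cluster_size=6)
        assert asg.n_clusters == 0
        assert set(asg.labels.values()) == {0}
        assert set(asg.unassigned) == set(dm.pair_ids)

    def test_label_multiset_invariant_under_input_permutation(self, noisy_network):
        net, _ = noisy_network
        dm = pairwise_dissimilarity(net)
        asg = hybrid_tree_cut(hierarchical_linkage(dm), dm)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(net))
        layers = [net.layers[i] for i in perm]
        net_p = build_multiplex(layers, net.cell_types)
        dm_p = pairwise_dissimilarity(net_p)
        asg_p = hybrid_tree_cut(hierarchical_linkage(dm_p), dm_p)
        by_pair = sorted(asg.labels.items())
        by_pair_p = sorted(asg_p.labels.items())
        # same pair ids get the same partition (up to label renaming)
        assert adjusted_rand_score(
            [l for _, l in by_pair], [l for _, l in by_pair_p]
        ) == 1.0

    @pytest.mark.parametrize("deep_split, mcs", [(5, 6), (-1, 6), (0, 0), (2.5, 6)])
    def test_parameter_validation(self, deep_split, mcs, noiseless_two_archetypes):
        net, _ = noiseless_two_archetypes
        dm = pairwise_dissimilarity(net)
        Z = hierarchical_linkage(dm)
        with pytest.raises(ValidationError):
            hybrid_tree_cut(Z, dm, deep_split=deep_split, min_cluster_size=mcs)

    def test_assigned_clusters_respect_min_size(self, noisy_network):
        net, _ = noisy_network
        dm = pairwise_dissimilarity(net)
        asg = hybrid_tree_cut(hierarchical_linkage(dm), dm, min_cluster_size=6)
        labels = np.array(list(asg.labels.values()))
        for lab in range(1, asg.n_clusters + 1):
            assert np.sum(labels == lab) >= 6

    def test_planted_recovery_with_noise_across_seeds(self):
        # mean ARI across seeds and archetype counts must stay high at 10% flips
        for K in (2, 3, 4):
            aris = []
            for seed in range(20):
                rng = np.random.default_rng(seed + 1000)
                members = int(rng.integers(6, 11))
                spec = ArchetypeSpec(
                    n_celltypes=6,
                    archetypes=random_archetypes(6, K, density=0.3, seed=seed + 500),
                    members_per_archetype=members,
                    edge_flip_prob=0.1,
                    seed=seed,
                )
                net, truth = generate_network(spec)
                dm = pairwise_dissimilarity(net)
                asg = hybrid_tree_cut(hierarchical_linkage(dm), dm)
                pred = [asg.labels[p] for p in net.pair_ids]
                gt = [truth[p] for p in net.pair_ids]
                aris.append(adjusted_rand_score(gt, pred))
            assert np.mean(aris) >= 0.9


class TestReferenceSemanticsFixtures:
    """Fixtures whose correct labels follow from the algorithm's semantics.

    Planted instances with within-group dissimilarity far below the
    between-group one must come out as exactly the planted groups; instances
    smaller than the minimum cluster size must stay fully unassigned.
    """

    @pytest.mark.parametrize("k,members,seed", [
        (2, 6, 0), (2, 8, 1), (3, 6, 2), (3, 7, 3), (4, 6, 4),
        (2, 10, 5), (3, 9, 6), (2, 7, 7),
    ])
    def test_separable_planted_instances(self, k, members, seed):
        spec = ArchetypeSpec(
            n_celltypes=6,
            archetypes=random_archetypes(6, k, density=1.0 / (k + 1), seed=seed,
                                         disjoint=True),
            members_per_archetype=members,
            weight_sigma=0.3,
            edge_flip_prob=0.0,
            seed=seed,
        )
        net, truth = generate_network(spec)
        dm = pairwise_dissimilarity(net)
        asg = hybrid_tree_cut(hierarchical_linkage(dm), dm)
        assert asg.n_clusters == k
        pred = [asg.labels[p] for p in net.pair_ids]
        gt = [truth[p] for p in net.pair_ids]
        assert adjusted_rand_score(gt, pred) == 1.0

    @pytest.mark.parametrize("n_layers,seed", [(3, 0), (4, 1), (5, 2)])
    def test_too_small_instances_all_unassigned(self, n_layers, seed):
        rng = np.random.default_rng(seed)
        dm = pairwise_dissimilarity(random_network(rng, n_layers=n_layers))
        asg = hybrid_tree_cut(hierarchical_linkage(dm), dm, min_cluster_size=6)
        assert set(asg.labels.values()) == {0}


class TestEstimator:
    def test_sklearn_protocol(self, noiseless_two_archetypes):
        net, _ = noiseless_two_archetypes
        dm = pairwise_dissimilarity(net)
        est = HybridTreeCut(min_cluster_size=6)
        assert est.get_params()["deep_split"] == 0
        est2 = clone(est).set_params(deep_split=1)
        assert est2.get_params()["deep_split"] == 1
        labels = est.fit_predict(dm.values)
        assert labels.shape == (len(net),)
        assert est.n_clusters_ == 2
        assert est.linkage_.shape == (len(net) - 1, 4)

    def test_rejects_invalid_input(self):
        est = HybridTreeCut()
        with pytest.raises(ValidationError):
            est.fit(np.array([[0, 0.5, 0.1], [0.5, 0, 0.2]]))
        with pytest.raises(ValidationError):
            est.fit(np.array([[0, 0.5], [0.1, 0]]))


class TestAveragePattern:
    def test_identical_members_reproduce_the_layer(self, cts_abc):
        layers = [make_layer(f"p{k}", {("A", "B"): 2.0}, cts_abc) for k in range(3)]
        net = build_multiplex(layers, cts_abc)
        from comunetx.cluster import ClusterAssignment

        asg = ClusterAssignment(labels={p: 1 for p in net.pair_ids},
                                linkage=np.zeros((2, 4)), n_clusters=1)
        pat = average_pattern(net, asg, 1)
        assert np.array_equal(pat.mean_weights, layers[0].weights)
        assert pat.member_ids == net.pair_ids

    def test_arithmetic_mean(self, cts_abc):
        net = build_multiplex(
            [make_layer("p1", {("A", "B"): 2.0}, cts_abc),
             make_layer("p2", {("A", "B"): 4.0}, cts_abc)],
            cts_abc,
        )
        from comunetx.cluster import ClusterAssignment

        asg = ClusterAssignment(labels={"p1": 1, "p2": 1},
                                linkage=np.zeros((1, 4)), n_clusters=1)
        pat = average_pattern(net, asg, 1)
        assert pat.mean_weights[0, 1] == 3.0

    def test_mean_delta_commutes_with_node_delta(self, noisy_network):
        net, _ = noisy_network
        dm = pairwise_dissimilarity(net)
        asg = hybrid_tree_cut(hierarchical_linkage(dm), dm)
        from comunetx import build_layer

        for lab in range(1, asg.n_clusters + 1):
            pat = average_pattern(net, asg, lab)
            mean_layer = build_layer("mean", pat.mean_weights, net.cell_types)
            direct = node_delta(mean_layer)
            for ct in net.cell_types:
                assert pat.mean_delta[ct] == pytest.approx(direct[ct], abs=1e-12)

    def test_unknown_label(self, noisy_network):
        net, _ = noisy_network
        dm = pairwise_dissimilarity(net)
        asg = hybrid_tree_cut(hierarchical_linkage(dm), dm)
        with pytest.raises(KeyError):
            average_pattern(net, asg, 99)


class TestEmbedding:
    def test_shape_and_determinism_mds(self, noisy_network):
        net, _ = noisy_network
        dm = pairwise_dissimilarity(net)
        c1, m1 = embed_layers(dm, seed=7, method="mds")
        c2, m2 = embed_layers(dm, seed=7, method="mds")
        assert c1.shape == (len(net), 2)
        assert np.all(np.isfinite(c1))
        assert np.array_equal(c1, c2)
        assert m1 == m2 == "mds"

    def test_planted_archetypes_separate(self, noiseless_two_archetypes):
        net, truth = noiseless_two_archetypes
        dm = pairwise_dissimilarity(net)
        coords, _ = embed_layers(dm, seed=3, method="mds")
        gt = np.array([truth[p] for p in net.pair_ids])
        c1, c2 = coords[gt == 1], coords[gt == 2]
        centroid_gap = np.linalg.norm(c1.mean(0) - c2.mean(0))
        spread = max(
            np.linalg.norm(c1 - c1.mean(0), axis=1).mean(),
            np.linalg.norm(c2 - c2.mean(0), axis=1).mean(),
        )
        assert centroid_gap > spread

    def test_umap_path_deterministic(self, noisy_network):
        pytest.importorskip("umap")
        net, _ = noisy_network
        dm = pairwise_dissimilarity(net)
        c1, m1 = embed_layers(dm, seed=11, method="umap")
        c2, _ = embed_layers(dm, seed=11, method="umap")
        assert m1 == "umap"
        assert c1.shape == (len(net), 2)
        assert np.array_equal(c1, c2)

    def test_too_few_layers(self, cts_abc):
        dm = DissimilarityMatrix(
            values=np.array([[0, 0.5], [0.5, 0]]), pair_ids=("a", "b")
        )
        with pytest.raises(ValidationError):
            embed_layers(dm, seed=0)
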