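"""HS-Tree construction, the cluster-node rule, representatives and the
per-tree candidate."""

import math

import numpy as np
import pytest

from hsforest import (
    DistanceCache,
    TreeParams,
    build_tree,
    is_cluster_node,
    select_representative,
    tree_candidate,
)
from hsforest.hashing import build_hash_function, select_pivots
from hsforest.synthetic import SyntheticSpec, generate_decoy_set
from hsforest.tree import HSTreeNode, largest_clusters

from conftest import random_chain
from test_hashing import pivot_index_from_rows


def make_forest_inputs(coords, p, seed):
    cache = DistanceCache(coords)
    rng = np.random.default_rng(seed)
    piv = select_pivots(cache, p, rng)
    pool = [build_hash_function(piv, r) for r in range(p)]
    return cache, piv, pool, rng


class TestIsClusterNode:
    def test_root_never_qualifies(self):
        assert not is_cluster_node(h=0, z=100, h_max=10, big_z=100)

    def test_singleton_always_qualifies(self):
        assert is_cluster_node(h=1, z=1, h_max=10, big_z=100)

    def test_threshold_evaluation(self):
        # log(30)/log(1000) ~ 0.4924: h=10/H=20 passes, h=9 fails
        assert is_cluster_node(h=10, z=30, h_max=20, big_z=1000)
        assert not is_cluster_node(h=9, z=30, h_max=20, big_z=1000)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            is_cluster_node(h=1, z=1, h_max=1, big_z=1)
        with pytest.raises(ValueError):
            is_cluster_node(h=-1, z=1, h_max=1, big_z=2)
        with pytest.raises(ValueError):
            is_cluster_node(h=1, z=5, h_max=1, big_z=4)


class TestBuildTree:
    def test_two_decoys_forced_singletons(self, rng):
        coords = np.stack([random_chain(5, rng) for _ in range(2)])
        cache, piv, pool, r = make_forest_inputs(coords, 2, 0)
        tree = build_tree(piv, pool, TreeParams(h_max=1, s=1, e=1), r)
        assert len(tree.cluster_nodes) == 2
        assert all(n.z == 1 and n.h == 1 for n in tree.cluster_nodes)

    def test_same_seed_same_tree(self, small_set):
        dset, _ = small_set
        coords = dset.coords_array()

        def run():
            cache, piv, pool, r = make_forest_inputs(coords, 10, 4)
            tree = build_tree(piv, pool, TreeParams(h_max=5, s=5, e=3), r)
            return [(n.h, n.members.tolist()) for n in tree.cluster_nodes]

        assert run() == run()

    def test_cluster_nodes_are_leaves_and_disjoint(self, small_set):
        dset, _ = small_set
        cache, piv, pool, r = make_forest_inputs(dset.coords_array(), 10, 1)
        tree = build_tree(piv, pool, TreeParams(h_max=5, s=5, e=3), r)
        seen = set()
        for node in tree.cluster_nodes:
            assert node.is_cluster and not node.children
            members = set(node.members.tolist())
            assert not members & seen
            seen |= members

    def test_at_most_one_cluster_node_per_path(self, small_set):
        """No cluster node is an ancestor of another (stop-on-satisfy)."""
        dset, _ = small_set
        cache, piv, pool, r = make_forest_inputs(dset.coords_array(), 12, 2)
        tree = build_tree(piv, pool, TreeParams(h_max=6, s=5, e=3), r)

        def walk(node, seen_cluster):
            if node.is_cluster:
                assert not seen_cluster
                seen_cluster = True
            for c in node.children:
                walk(c, seen_cluster)

        walk(tree.root, False)

    def test_partial_clustering_allowed(self, small_set):
        """The union of cluster members may be a strict subset of the set."""
        dset, _ = small_set
        cache, piv, pool, r = make_forest_inputs(dset.coords_array(), 10, 3)
        tree = build_tree(piv, pool, TreeParams(h_max=5, s=5, e=3), r)
        covered = sum(n.z for n in tree.cluster_nodes)
        assert covered <= dset.n  # strict subset in most runs; never more

    def test_children_partition_parent(self, small_set):
        dset, _ = small_set
        cache, piv, pool, r = make_forest_inputs(dset.coords_array(), 10, 5)
        tree = build_tree(piv, pool, TreeParams(h_max=5, s=5, e=3), r)

        def walk(node):
            if node.children:
                merged = np.sort(np.concatenate([c.members for c in node.children]))
                assert np.array_equal(merged, np.sort(node.members))
                assert all(c.h == node.h + 1 for c in node.children)
                for c in node.children:
                    walk(c)

        walk(tree.root)

    def test_well_separated_clusters_give_pure_nodes(self):
        """On two well-separated synthetic clusters, cluster nodes are
        ground-truth pure in >= 95% of seeded runs.

        The tree is grown deep (H_max close to P) so each tree almost
        surely draws at least one hash function whose median falls on the
        cluster boundary; shallow trees can miss every boundary splitter
        and stop on a mixed node.
        """
        spec = SyntheticSpec(
            n_res=25,
            cluster_sizes=(120, 80),
            cluster_center_rmsd=(2.0, 7.0),
            within_cluster_sigma=0.6,
            outlier_fraction=0.0,
            seed=42,
        )
        dset, labels = generate_decoy_set(spec)
        coords = dset.coords_array()
        pure_runs = 0
        for seed in range(50):
            cache, piv, pool, r = make_forest_inputs(coords, 10, seed)
            tree = build_tree(piv, pool, TreeParams(h_max=7, s=5, e=3), r)
            pure = all(
                len(set(labels[node.members].tolist())) == 1
                for node in tree.cluster_nodes
            )
            pure_runs += pure
        assert pure_runs >= 0.95 * 50

    def test_exact_height_always_yields_cluster_node(self, rng):
        """Fuzz: with the exact tree height, every tree has >= 1 cluster
        node, over random sets of varied size."""
        for trial in range(40):
            n = int(rng.integers(2, 60))
            coords = np.stack([random_chain(4, rng) for _ in range(n)])
            p = min(n, 12)
            cache, piv, pool, r = make_forest_inputs(coords, p, trial)
            tree = build_tree(
                piv, pool, TreeParams(h_max=max(1, p // 2), s=1, e=1), r,
                exact_height=True,
            )
            assert len(tree.cluster_nodes) >= 1


class TestRepresentative:
    def test_singleton(self):
        piv = pivot_index_from_rows([[7.1, 5.0, 9.2]])
        node = HSTreeNode(members=np.array([2]), h=1)
        assert select_representative(node, piv) == 2

    def test_argmin_of_pivot_sums(self):
        piv = pivot_index_from_rows([[7.1, 5.0, 9.2]])
        node = HSTreeNode(members=np.array([0, 1, 2]), h=1)
        assert select_representative(node, piv) == 1

    def test_tie_goes_to_lowest_index(self):
        piv = pivot_index_from_rows([[5.0, 3.0, 3.0, 6.0]])
        node = HSTreeNode(members=np.array([2, 1]), h=1)
        assert select_representative(node, piv) == 1


class TestTreeCandidate:
    def test_single_cluster_returns_its_representative(self, small_set):
        dset, _ = small_set
        cache, piv, pool, r = make_forest_inputs(dset.coords_array(), 10, 6)
        tree = build_tree(piv, pool, TreeParams(h_max=5, s=5, e=3), r)
        tree.cluster_nodes = tree.cluster_nodes[:1]
        rep = select_representative(tree.cluster_nodes[0], piv)
        cand = tree_candidate(tree, piv, cache, TreeParams(h_max=5, s=5, e=3), [0, 1, 2])
        assert cand == rep

    def test_ranking_by_total_distance_to_low_energy(self, small_set):
        """S=2, E=1: the representative closer to the low-energy decoy wins."""
        dset, _ = small_set
        cache, piv, pool, r = make_forest_inputs(dset.coords_array(), 10, 7)
        tree = build_tree(piv, pool, TreeParams(h_max=5, s=2, e=1), r)
        params = TreeParams(h_max=5, s=2, e=1)
        reps = [select_representative(n, piv) for n in largest_clusters(tree, 2)]
        e0 = 5
        cand = tree_candidate(tree, piv, cache, params, [e0])
        dists = {rp: cache.pair(rp, e0) for rp in reps}
        assert cand == min(reps, key=lambda rp: (dists[rp], rp))

    def test_largest_clusters_size_then_discovery_order(self, small_set):
        dset, _ = small_set
        cache, piv, pool, r = make_forest_inputs(dset.coords_array(), 10, 8)
        tree = build_tree(piv, pool, TreeParams(h_max=5, s=3, e=3), r)
        top = largest_clusters(tree, 3)
        sizes = [n.z for n in top]
        assert sizes == sorted(sizes, reverse=True)
        assert all(n.z <= sizes[-1] for n in tree.cluster_nodes if n not in top)

    def test_representative_that_is_low_energy_decoy_self_distance_zero(self, small_set):
        dset, _ = small_set
        cache, piv, pool, r = make_forest_inputs(dset.coords_array(), 10, 9)
        tree = build_tree(piv, pool, TreeParams(h_max=5, s=1, e=2), r)
        tree.cluster_nodes = tree.cluster_nodes[:1]
        rep = select_representative(tree.cluster_nodes[0], piv)
        other = (rep + 1) % dset.n
        cand = tree_candidate(tree, piv, cache, TreeParams(h_max=5, s=1, e=2), [rep, other])
        assert cand == rep  # total = 0 + d(rep, other) but only candidate anyway
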