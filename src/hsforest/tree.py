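"""One randomized HS-Tree: median-split descent, cluster-node detection,
representative extraction and the per-tree candidate.

"HS" stands for Height and Size, the two quantities balanced by the
cluster-node rule: a node v at height h(v) with z(v) members is a cluster
node when h(v)/H >= log z(v) / log Z, taken at the shallowest satisfying
node on each root-to-leaf path.  Height is a proxy for density (surviving
many median splits together means the members are mutually close), size
guards against accepting tiny accidental groups too early.  In production
the height bound H_max stands in for the true height H, which lets the
descent stop at the first satisfying node and build only a sliver of the
full tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .hashing import HashFunction, PivotIndex, hash_assign
from .metrics import DistanceCache


class EmptyResultError(RuntimeError):
    """Raised when a tree yields no cluster node.

    With the H_max approximation this is theoretically possible (though rare
    in practice); re-running with a smaller H_max resolves it.
    """


@dataclass
class TreeParams:
    """Per-tree knobs: height bound, clusters to rank, low-energy pool size."""

    h_max: int
    s: int = 30
    e: int = 10

    def __post_init__(self):
        if self.h_max < 1 or self.s < 1 or self.e < 1:
            raise ValueError("H_max, S and E must all be >= 1")


@dataclass(eq=False)  # identity semantics: nodes hold arrays
class HSTreeNode:
    members: np.ndarray
    h: int
    children: list["HSTreeNode"] = field(default_factory=list)
    is_cluster: bool = False

    @property
    def z(self) -> int:
        return len(self.members)


@dataclass
class HSTree:
    root: HSTreeNode
    level_functions: list[HashFunction]
    cluster_nodes: list[HSTreeNode]
    height: int  # max leaf depth actually built
    candidate: Optional[int] = None


def is_cluster_node(h: int, z: int, h_max: int, big_z: int) -> bool:
    """Cluster-node rule: ``h / h_max >= log(z) / log(big_z)``.

    ``big_z`` is the whole set size.  The ratio is log-base invariant; the
    root (h=0, z=Z) never qualifies, a singleton at any h >= 1 always does.
    """
    if big_z < 2:
        raise ValueError("set size Z must be >= 2")
    if h_max < 1:
        raise ValueError("H_max must be >= 1")
    if not 1 <= z <= big_z:
        raise ValueError(f"node size {z} outside [1, {big_z}]")
    if h < 0:
        raise ValueError("height must be >= 0")
    return h / h_max >= math.log(z) / math.log(big_z)


def _sample_level_functions(
    hash_pool: Sequence[HashFunction], k: int, rng: np.random.Generator
) -> list[HashFunction]:
    idx = rng.choice(len(hash_pool), size=k, replace=False)
    return [hash_pool[int(i)] for i in idx]


def build_tree(
    pivots: PivotIndex,
    hash_pool: Sequence[HashFunction],
    params: TreeParams,
    rng: np.random.Generator,
    *,
    exact_height: bool = False,
) -> HSTree:
    """Grow one HS-Tree over the full decoy set.

    Each level uses a single hash function sampled without replacement from
    ``hash_pool``; descent is depth-first, bin0 first, so cluster nodes are
    recorded in a deterministic first-found order.  A node becomes a leaf
    when the cluster rule fires (flagged ``is_cluster``), at depth ``h_max``,
    or when its split is degenerate (one empty bin, from tied distances).

    With ``exact_height=True`` the tree is grown fully (ignoring the cluster
    rule, splitting until singleton/degenerate/levels exhausted, with the
    whole pool available) and cluster nodes are then found top-down using
    the realised tree height H in place of H_max.  This is the mode in which
    at least one cluster node is guaranteed: the deepest leaf always
    satisfies h/H = 1 >= log(z)/log(Z).
    """
    n = pivots.dist_matrix.shape[1]
    if n < 2:
        raise ValueError("need at least 2 decoys")
    big_z = n
    if exact_height:
        level_functions = _sample_level_functions(hash_pool, len(hash_pool), rng)
    else:
        if params.h_max > len(hash_pool):
            raise ValueError(
                f"H_max={params.h_max} exceeds pool of {len(hash_pool)} hash functions"
            )
        level_functions = _sample_level_functions(hash_pool, params.h_max, rng)

    root = HSTreeNode(members=np.arange(n), h=0)
    cluster_nodes: list[HSTreeNode] = []
    height = 0

    def grow(node: HSTreeNode) -> None:
        nonlocal height
        height = max(height, node.h)
        if not exact_height:
            if node.h >= 1 and is_cluster_node(node.h, node.z, params.h_max, big_z):
                node.is_cluster = True
                cluster_nodes.append(node)
                return
            if node.h == params.h_max:
                return
        else:
            if node.z == 1 or node.h == len(level_functions):
                return
        fn = level_functions[node.h]
        bin0, bin1 = hash_assign(fn, pivots, node.members)
        if len(bin0) == 0 or len(bin1) == 0:
            return  # unsplittable: tied distances exhaust this path
        node.children = [
            HSTreeNode(members=bin0, h=node.h + 1),
            HSTreeNode(members=bin1, h=node.h + 1),
        ]
        for child in node.children:
            grow(child)

    grow(root)

    if exact_height:
        h_eff = max(height, 1)

        def find(node: HSTreeNode) -> None:
            if node.h >= 1 and is_cluster_node(node.h, node.z, h_eff, big_z):
                node.is_cluster = True
                cluster_nodes.append(node)
                return
            for child in node.children:
                find(child)

        find(root)

    if not cluster_nodes:
        raise EmptyResultError(
            "tree produced no cluster nodes; re-run with a smaller H_max"
        )
    return HSTree(
        root=root,
        level_functions=level_functions,
        cluster_nodes=cluster_nodes,
        height=height,
    )


def select_representative(node: HSTreeNode, pivots: PivotIndex) -> int:
    """Cluster representative: member with the smallest total distance to the
    pivots (precomputed column sums — zero new distance evaluations).
    Ties break to the lowest decoy index."""
    members = np.asarray(node.members)
    if members.size == 0:
        raise ValueError("node has no members")
    sums = pivots.column_sums[members]
    best = sums.min()
    return int(members[np.isclose(sums, best)].min())


def largest_clusters(tree: HSTree, s: int) -> list[HSTreeNode]:
    """The ``min(s, #clusters)`` largest cluster nodes; size ties break by
    discovery (depth-first) order for seed-determinism."""
    order = sorted(range(len(tree.cluster_nodes)), key=lambda i: (-tree.cluster_nodes[i].z, i))
    return [tree.cluster_nodes[i] for i in order[:s]]


def tree_candidate(
    tree: HSTree,
    pivots: PivotIndex,
    cache: DistanceCache,
    params: TreeParams,
    low_energy_ids: Sequence[int],
) -> int:
    """The tree's candidate: among representatives of the S largest cluster
    nodes, the one with the smallest total distance to the E lowest-energy
    decoys.  Charges at most S·E new distance evaluations; a representative
    that is itself a low-energy decoy contributes 0 to its own total."""
    reps = [select_representative(node, pivots) for node in largest_clusters(tree, params.s)]
    totals = [sum(cache.pair(r, int(e)) for e in low_energy_ids) for r in reps]
    best = min(totals)
    tree.candidate = min(r for r, t in zip(reps, totals) if np.isclose(t, best))
    return tree.candidate
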