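"""Pivot selection and median-split hashing functions.

The locality-sensitive hashing here exploits a basic metric-space property:
two similar decoys usually have similar distances to any third decoy.  Each
randomly chosen pivot decoy therefore induces a binary hash — is a decoy's
distance to the pivot below the pivot's median distance, or not — and
same-cluster decoys tend to land in the same bin more often than
cross-cluster ones.  The median threshold keeps the bins balanced, which is
what bounds the tree height downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import DistanceCache


@dataclass
class PivotIndex:
    """P pivots with their full P×N distance matrix.

    ``column_sums[j]`` is decoy ``j``'s total distance to all pivots; it is
    reused both for cluster-representative selection and as the consensus
    pseudo-energy, at zero additional distance evaluations.
    """

    pivot_ids: np.ndarray  # (P,) decoy indices
    dist_matrix: np.ndarray  # (P, N)
    column_sums: np.ndarray  # (N,)

    @property
    def p(self) -> int:
        return len(self.pivot_ids)


@dataclass(frozen=True)
class HashFunction:
    """One median-split hash: bin by distance to a pivot vs. its median."""

    pivot_row: int
    threshold: float


def select_pivots(cache: DistanceCache, p: int, rng: np.random.Generator) -> PivotIndex:
    """Sample ``p`` distinct pivots uniformly and fill their distance rows.

    Charges at most P·N distance evaluations on the cache (self-distances
    are 0 by definition and pivot-pivot pairs are evaluated once).
    """
    n = cache.n
    if not 1 <= p <= n:
        raise ValueError(f"need 1 <= P <= N, got P={p}, N={n}")
    pivot_ids = np.sort(rng.choice(n, size=p, replace=False))
    rows = [cache.row(int(i)) for i in pivot_ids]
    dist_matrix = np.stack(rows)
    return PivotIndex(
        pivot_ids=pivot_ids,
        dist_matrix=dist_matrix,
        column_sums=dist_matrix.sum(axis=0),
    )


def build_hash_function(pivots: PivotIndex, row: int) -> HashFunction:
    """Hash function for pivot ``row``: threshold = lower-upper median.

    The threshold is the sorted distance at 0-based index ⌊N/2⌋.  Combined
    with the strict ``<`` split this yields ⌊N/2⌋ | ⌈N/2⌉ bins for distinct
    distances, so neither bin exceeds 2N/3 (equality only at N = 3).
    """
    dists = pivots.dist_matrix[row]
    threshold = float(np.sort(dists)[len(dists) // 2])
    return HashFunction(pivot_row=row, threshold=threshold)


def hash_assign(
    h: HashFunction, pivots: PivotIndex, members: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split ``members`` into (below-median, at-or-above-median) bins.

    ``bin0 = {j : d(pivot, j) < threshold}``; ties go to ``bin1``.  The bins
    are a disjoint cover of ``members`` preserving input order.  A row of
    all-equal distances yields an empty ``bin0``; the tree treats such a
    node as unsplittable.
    """
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("members must be non-empty")
    d = pivots.dist_matrix[h.pivot_row, members]
    below = d < h.threshold
    return members[below], members[~below]
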