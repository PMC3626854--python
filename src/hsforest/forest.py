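"""HS-Forest orchestration: pivots → T randomized trees → per-tree
candidates → consensus pick.

The public surface follows the model/results idiom: :class:`HSForest` is
built from a :class:`~hsforest.io.DecoySet` (or a decoy directory) and
``fit()`` returns a :class:`SelectionResult` carrying the selected decoy,
the per-tree candidates, cluster diagnostics and the distance-evaluation
count, with a ``summary()`` table.  The module-level functions
(:func:`run_hs_forest`, :func:`consensus_select`, :func:`consensus_energy`)
remain usable directly.

Distance budget: a run evaluates at most ``P·N + T·S·E + C(T,2)`` unique
decoy pairs — the pivot matrix, per-tree candidate ranking, and the final
consensus — versus ``N(N-1)/2`` for a full distance matrix.  No full
pairwise matrix is ever materialised.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .hashing import PivotIndex, build_hash_function, select_pivots
from .io import DecoySet, Structure, read_decoy_set, write_selection_report
from .metrics import DistanceCache
from .tree import HSTree, TreeParams, build_tree, tree_candidate

_DISTANCES = ("ca_rmsd", "gdt_ts_distance")


@dataclass
class ForestParams:
    """Forest-level parameters.

    Defaults follow the recommended operating point: P=40 pivots, T=30
    trees, S=30 clusters ranked per tree, E=10 lowest-energy decoys, and
    H_max = P/2 so each tree draws a partially different set of hashing
    functions.  ``distance`` selects the metric used everywhere (pivot
    matrix, candidate ranking, consensus).
    """

    p: int = 40
    t: int = 30
    s: int = 30
    e: int = 10
    h_max: Optional[int] = None
    seed: int = 0
    distance: str = "ca_rmsd"

    def __post_init__(self):
        if self.h_max is None:
            self.h_max = max(1, self.p // 2)
        if min(self.p, self.t, self.s, self.e, self.h_max) < 1:
            raise ValueError("P, T, S, E and H_max must all be >= 1")
        if self.h_max > self.p:
            raise ValueError(f"H_max={self.h_max} must not exceed P={self.p}")
        if self.distance not in _DISTANCES:
            raise ValueError(f"distance must be one of {_DISTANCES}")

    def budget(self, n: int) -> int:
        """Upper bound on unique-pair distance evaluations for a set of n."""
        return self.p * n + self.t * self.s * self.e + math.comb(self.t, 2)

    def to_dict(self) -> dict:
        return {
            "P": self.p,
            "T": self.t,
            "S": self.s,
            "E": self.e,
            "H_max": self.h_max,
            "seed": self.seed,
            "distance": self.distance,
        }


@dataclass
class SelectionResult:
    """Outcome of one HS-Forest run.

    ``consensus`` / ``consensus_id`` identify the selected decoy; it is
    always one of ``candidates`` (the per-tree picks, with multiplicity).
    ``tree_summaries`` records cluster-node count and the largest cluster
    sizes for each tree; ``eval_count`` is the number of unique decoy pairs
    whose distance was actually computed.
    """

    consensus: int
    consensus_id: str
    candidates: list[int]
    candidate_ids: list[str]
    tree_summaries: list[dict]
    eval_count: int
    eval_budget: int
    n_decoys: int
    params: ForestParams
    energy_source: str
    low_energy_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected_decoy": self.consensus_id,
            "candidates": self.candidate_ids,
            "trees": self.tree_summaries,
            "eval_count": self.eval_count,
            "eval_budget": self.eval_budget,
            "n_decoys": self.n_decoys,
            "energy_source": self.energy_source,
            "low_energy_decoys": self.low_energy_ids,
            "params": self.params.to_dict(),
        }

    def save(self, path) -> None:
        """Write the deterministic JSON report."""
        write_selection_report(self, path)

    def summary(self) -> str:
        votes = Counter(self.candidate_ids)
        lines = [
            "HS-Forest selection",
            "=" * 52,
            f"selected decoy:       {self.consensus_id}",
            f"decoys:               {self.n_decoys}",
            f"trees:                {self.params.t}",
            f"energy source:        {self.energy_source}",
            f"distance metric:      {self.params.distance}",
            f"distance evaluations: {self.eval_count} (budget {self.eval_budget})",
            f"seed:                 {self.params.seed}",
            "",
            "candidate votes:",
        ]
        for cid, cnt in votes.most_common():
            lines.append(f"  {cid:<24s} {cnt:3d}/{self.params.t}")
        sizes = [t["n_cluster_nodes"] for t in self.tree_summaries]
        lines.append("")
        lines.append(
            f"cluster nodes per tree: min {min(sizes)}, "
            f"median {int(np.median(sizes))}, max {max(sizes)}"
        )
        return "\n".join(lines)

    def plot_cluster_sizes(self, ax=None):
        """Bar plot of the largest cluster sizes found by each tree."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        top = [t["largest_cluster_sizes"][0] for t in self.tree_summaries]
        ax.bar(range(len(top)), top)
        ax.set_xlabel("tree")
        ax.set_ylabel("largest cluster size")
        ax.set_title("HS-Forest cluster diagnostics")
        return ax


def consensus_select(candidates: Sequence[int], cache: DistanceCache) -> int:
    """Candidate minimising the total distance to all candidates.

    Multiplicity counts: duplicated candidates contribute 0 to themselves
    and pull the consensus toward themselves (a vote).  Ties break to the
    lowest decoy index.  Charges at most C(U, 2) evaluations for U distinct
    candidates.
    """
    if len(candidates) == 0:
        raise ValueError("need at least one candidate")
    mult = Counter(int(c) for c in candidates)
    distinct = sorted(mult)
    totals = {
        c: sum(m * cache.pair(c, other) for other, m in mult.items() if other != c)
        for c in distinct
    }
    best = min(totals.values())
    return min(c for c, t in totals.items() if np.isclose(t, best))


def consensus_energy(pivots: PivotIndex) -> np.ndarray:
    """Consensus pseudo-energy: each decoy's total distance to the pivot
    reference structures (lower = better).  Free — the column sums of the
    pivot matrix already exist."""
    return pivots.column_sums.copy()


def _lowest_energy_indices(energy: np.ndarray, e: int) -> np.ndarray:
    """Indices of the E lowest energies; ties break to the lower index."""
    finite = np.flatnonzero(np.isfinite(energy))
    order = finite[np.argsort(energy[finite], kind="stable")]
    return order[:e]


def run_hs_forest(
    decoy_set: DecoySet,
    params: ForestParams,
    energies: Optional[Mapping[str, float]] = None,
    cache: Optional[DistanceCache] = None,
) -> SelectionResult:
    """Execute the full pipeline on a decoy set.

    ``energies`` maps decoy id → energy (lower = better); when absent (and
    the set itself carries none), the consensus pseudo-energy derived from
    the pivots is used.  Deterministic given (inputs, seed).
    """
    n = decoy_set.n
    if n < 2:
        raise ValueError("need at least 2 decoys")
    if params.p > n:
        raise ValueError(f"P={params.p} exceeds set size N={n}")
    if cache is None:
        cache = DistanceCache(decoy_set.coords_array(), metric=params.distance)
    rng = np.random.default_rng(params.seed)

    pivots = select_pivots(cache, params.p, rng)
    hash_pool = [build_hash_function(pivots, r) for r in range(params.p)]

    energy_vec = None
    if energies is not None:
        energy_vec = np.array(
            [float(energies[i]) if i in energies else np.nan for i in decoy_set.ids]
        )
        if not np.any(np.isfinite(energy_vec)):
            energy_vec = None
    if energy_vec is None:
        set_energy = decoy_set.energies()
        energy_vec = set_energy if set_energy is not None else None
    if energy_vec is None:
        energy_vec = consensus_energy(pivots)
        energy_source = "consensus"
    else:
        energy_source = "table"

    low_energy = _lowest_energy_indices(energy_vec, params.e)
    tree_params = TreeParams(h_max=params.h_max, s=params.s, e=params.e)

    candidates: list[int] = []
    tree_summaries: list[dict] = []
    for _ in range(params.t):
        tree = build_tree(pivots, hash_pool, tree_params, rng)
        cand = tree_candidate(tree, pivots, cache, tree_params, low_energy)
        candidates.append(cand)
        sizes = sorted((node.z for node in tree.cluster_nodes), reverse=True)
        tree_summaries.append(
            {
                "candidate": decoy_set.ids[cand],
                "n_cluster_nodes": len(tree.cluster_nodes),
                "largest_cluster_sizes": sizes[: params.s],
                "height": tree.height,
            }
        )

    consensus = consensus_select(candidates, cache)
    budget = params.budget(n)
    assert cache.eval_count <= budget, "distance budget exceeded"
    ids = decoy_set.ids
    return SelectionResult(
        consensus=consensus,
        consensus_id=ids[consensus],
        candidates=candidates,
        candidate_ids=[ids[c] for c in candidates],
        tree_summaries=tree_summaries,
        eval_count=cache.eval_count,
        eval_budget=budget,
        n_decoys=n,
        params=params,
        energy_source=energy_source,
        low_energy_ids=[ids[int(i)] for i in low_energy],
    )


class HSForest:
    """HS-Forest decoy-selection model over a decoy set.

    Parameters
    ----------
    decoy_set : DecoySet
    energies : mapping id -> energy, optional
        Overrides any energies carried by the set's structures.
    **params
        Forest parameters (``p``, ``t``, ``s``, ``e``, ``h_max``, ``seed``,
        ``distance``), see :class:`ForestParams`.

    Examples
    --------
    >>> model = HSForest(decoy_set, p=10, t=5, s=5, e=3)
    >>> res = model.fit(seed=1)
    >>> print(res.summary())          # doctest: +SKIP
    """

    def __init__(self, decoy_set: DecoySet, energies=None, **params):
        self.decoy_set = decoy_set
        self.energies = dict(energies) if energies is not None else None
        self.params = ForestParams(**params)

    @classmethod
    def from_directory(cls, decoy_dir, energy_table=None, native=None, **params):
        """Build the model from a directory of PDB decoys."""
        dset = read_decoy_set(decoy_dir, energy_table=energy_table, native=native)
        return cls(dset, **params)

    def fit(self, seed: Optional[int] = None) -> SelectionResult:
        """Run the selection; ``seed`` overrides the params' seed."""
        params = self.params if seed is None else replace(self.params, seed=seed)
        return run_hs_forest(self.decoy_set, params, energies=self.energies)
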