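"""Pairwise structure distances: Cα RMSD under optimal superposition and GDT-TS.

All distances operate on plain ``(N, 3)`` float arrays of Cα coordinates in
Ångströms (see :class:`hsforest.io.Structure`).  The :class:`DistanceCache`
wraps a chosen metric with memoisation and an evaluation counter; the counter
is what the forest's distance-budget invariant is asserted against, so a
cached pair never increments it.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

#: GDT-TS distance cutoffs in Å, averaged with equal weight.
GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)

_METRIC_NAMES = ("ca_rmsd", "gdt_ts_distance")


def _as_coords(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"coordinates must be (N, 3), got {X.shape}")
    if X.shape[0] < 3:
        raise ValueError(f"need at least 3 residues, got {X.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("coordinates contain non-finite values")
    return X


def _check_pair(A, B) -> tuple[np.ndarray, np.ndarray]:
    A = _as_coords(A)
    B = _as_coords(B)
    if A.shape[0] != B.shape[0]:
        raise ValueError(
            f"structures have different lengths: {A.shape[0]} vs {B.shape[0]}"
        )
    return A, B


def kabsch_superpose(A, B) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``A`` onto ``B``.

    Returns ``(R, t, rmsd)`` where ``R`` is a proper rotation (det +1) and
    ``t`` a translation such that ``R @ a + t`` best matches ``B`` in the
    least-squares sense, and ``rmsd = sqrt(mean ||R a_i + t - b_i||^2)`` is
    the minimum over all rigid transforms.  Reflections are excluded by the
    determinant sign correction, so mirror-image structures do not collapse
    to zero distance.
    """
    A, B = _check_pair(A, B)
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = A0.T @ B0
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = A0 @ R.T - B0
    rmsd = float(np.sqrt((diff * diff).sum() / A.shape[0]))
    return R, t, rmsd


def ca_rmsd(A, B) -> float:
    """Cα RMSD after optimal superposition (a metric up to rigid motion)."""
    return kabsch_superpose(A, B)[2]


def ca_rmsd_many(A, Bs: np.ndarray) -> np.ndarray:
    """Cα RMSD of one structure against a stack of structures.

    ``A`` is ``(N, 3)``; ``Bs`` is ``(M, N, 3)``.  Uses the singular-value
    form of the Kabsch minimum (with reflection correction on the smallest
    singular value) so no rotation matrices are materialised; this is the
    fast path used to fill pivot distance rows.
    """
    A = _as_coords(A)
    Bs = np.asarray(Bs, dtype=float)
    if Bs.ndim != 3 or Bs.shape[1:] != A.shape:
        raise ValueError(f"expected stack of shape (M, {A.shape[0]}, 3)")
    n = A.shape[0]
    A0 = A - A.mean(axis=0)
    B0 = Bs - Bs.mean(axis=1, keepdims=True)
    # covariance per pair: H_m = A0^T B0_m
    H = np.einsum("ni,mnj->mij", A0, B0)
    s = np.linalg.svd(H, compute_uv=False)  # (M, 3) descending
    det = np.linalg.det(H)
    sgn = np.where(det < 0, -1.0, 1.0)
    trace = s[:, 0] + s[:, 1] + sgn * s[:, 2]
    e0 = (A0 * A0).sum() + (B0 * B0).sum(axis=(1, 2))
    msd = np.maximum(e0 - 2.0 * trace, 0.0) / n
    return np.sqrt(msd)


def _gdt_seed_sets(n: int) -> list[np.ndarray]:
    """Superposition seeds: the full chain plus sliding windows of length
    3, 5 and N/2 (each at every offset)."""
    seeds = [np.arange(n)]
    for w in sorted({3, 5, max(3, n // 2)}):
        if w > n:
            continue
        for start in range(n - w + 1):
            seeds.append(np.arange(start, start + w))
    return seeds


def gdt_ts(A, B, max_refine: int = 10) -> float:
    """GDT-TS similarity in [0, 1] (higher = more similar).

    Mean over cutoffs 1/2/4/8 Å of the maximal fraction of residues that can
    be placed within the cutoff under a rigid superposition.  The maximum is
    approximated by a standard seed-and-refine heuristic: each seed (global
    fit plus sliding windows) is superposed, then iteratively re-fit on the
    residues currently within the cutoff until that set is stable.
    """
    A, B = _check_pair(A, B)
    n = A.shape[0]
    seeds = _gdt_seed_sets(n)
    fracs = []
    for cutoff in GDT_CUTOFFS:
        best = 0
        for seed in seeds:
            idx = seed
            prev: frozenset | None = None
            for _ in range(max_refine):
                if idx.size < 3:
                    break
                R, t, _ = kabsch_superpose(A[idx], B[idx])
                moved = A @ R.T + t
                within = np.linalg.norm(moved - B, axis=1) <= cutoff
                cur = frozenset(np.flatnonzero(within).tolist())
                if len(cur) > best:
                    best = len(cur)
                if cur == prev:
                    break
                prev = cur
                idx = np.flatnonzero(within)
        fracs.append(best / n)
    return float(np.mean(fracs))


def gdt_ts_distance(A, B) -> float:
    """Distance form of GDT-TS: ``1 - gdt_ts`` (0 for identical structures)."""
    return 1.0 - gdt_ts(A, B)


class DistanceCache:
    """Memoising, counting distance provider over an indexed decoy set.

    Parameters
    ----------
    coords : (N, L, 3) array or sequence of (L, 3) arrays
        Cα coordinates of all decoys in the working set.
    metric : {"ca_rmsd", "gdt_ts_distance"}

    ``eval_count`` counts *unique ordered-pair evaluations*: a memo hit, a
    self-distance, or a lookup into a previously charged pivot row is free.
    The selection pipeline's complexity guarantee is stated in terms of this
    counter.
    """

    def __init__(self, coords, metric: str = "ca_rmsd"):
        if metric not in _METRIC_NAMES:
            raise ValueError(f"unknown metric {metric!r}; choose from {_METRIC_NAMES}")
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (N, L, 3)")
        self.metric = metric
        self.eval_count = 0
        self._memo: dict[tuple[int, int], float] = {}
        self._rows: dict[int, np.ndarray] = {}

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def reset(self) -> None:
        self.eval_count = 0
        self._memo.clear()
        self._rows.clear()

    def _compute(self, i: int, j: int) -> float:
        if self.metric == "ca_rmsd":
            return ca_rmsd(self.coords[i], self.coords[j])
        return gdt_ts_distance(self.coords[i], self.coords[j])

    def pair(self, i: int, j: int) -> float:
        """Distance between decoys ``i`` and ``j`` (memoised)."""
        if i == j:
            return 0.0
        if i in self._rows:
            return float(self._rows[i][j])
        if j in self._rows:
            return float(self._rows[j][i])
        key = (i, j) if i < j else (j, i)
        val = self._memo.get(key)
        if val is None:
            val = self._compute(i, j)
            self._memo[key] = val
            self.eval_count += 1
        return float(val)

    def row(self, i: int) -> np.ndarray:
        """Distances from decoy ``i`` to every decoy, charging only pairs not
        already covered by an earlier row.  Used to fill the pivot matrix."""
        if i in self._rows:
            return self._rows[i]
        if self.metric == "ca_rmsd":
            out = ca_rmsd_many(self.coords[i], self.coords)
        else:
            out = np.array(
                [0.0 if j == i else self._compute(i, j) for j in range(self.n)]
            )
        out[i] = 0.0
        charged = self.n - 1
        for k, prior in self._rows.items():
            out[k] = prior[i]  # reuse symmetric value, keep rows consistent
            charged -= 1
        self.eval_count += charged
        self._rows[i] = out
        return out
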