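"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's SVD-based superposition path: the
rotation-grid oracle searches SO(3) directly (Euler-angle grid plus local
step-halving refinement, exact optimal translation by centroid matching),
and the GDT oracle enumerates every residue subset of size >= 3 as a
superposition seed.  Both are far too slow for production but give
trustworthy reference values on small inputs.
"""

from __future__ import annotations

import itertools

import numpy as np


def _euler_matrices(a, b, c):
    """Stack of Rz(a) @ Ry(b) @ Rz(c) rotation matrices (vectorised)."""
    a, b, c = np.broadcast_arrays(a, b, c)
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    R = np.empty(a.shape + (3, 3))
    R[..., 0, 0] = ca * cb * cc - sa * sc
    R[..., 0, 1] = -ca * cb * sc - sa * cc
    R[..., 0, 2] = ca * sb
    R[..., 1, 0] = sa * cb * cc + ca * sc
    R[..., 1, 1] = -sa * cb * sc + ca * cc
    R[..., 1, 2] = sa * sb
    R[..., 2, 0] = -sb * cc
    R[..., 2, 1] = sb * sc
    R[..., 2, 2] = cb
    return R


def _rmsd_under(R, A0, B0):
    """RMSD for each rotation in the stack (translation optimal = centroids)."""
    moved = np.einsum("...ij,nj->...ni", R, A0)
    diff = moved - B0
    return np.sqrt((diff * diff).sum(axis=(-1, -2)) / A0.shape[0])


def grid_rmsd(A, B, coarse_deg: float = 12.0, refine_steps: int = 40) -> float:
    """Minimum RMSD over rigid transforms by brute-force rotation search.

    Coarse Euler-angle grid (``coarse_deg`` spacing) to find the basin, then
    local 3x3x3 neighbourhood refinement with step halving down to ~1e-10
    rad.  Optimal translation is exact (centroid superposition) for every
    rotation, so only the rotation is searched.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    step = np.deg2rad(coarse_deg)
    aa = np.arange(0, 2 * np.pi, step)
    bb = np.arange(0, np.pi + step, step)
    cc = np.arange(0, 2 * np.pi, step)
    ga, gb, gc = np.meshgrid(aa, bb, cc, indexing="ij")
    vals = _rmsd_under(_euler_matrices(ga, gb, gc), A0, B0)
    k = np.unravel_index(np.argmin(vals), vals.shape)
    best = np.array([ga[k], gb[k], gc[k]])
    best_val = vals[k]
    offsets = np.array(list(itertools.product([-1, 0, 1], repeat=3)))
    for _ in range(refine_steps):
        step /= 2.0
        cand = best + offsets * step
        vals = _rmsd_under(
            _euler_matrices(cand[:, 0], cand[:, 1], cand[:, 2]), A0, B0
        )
        j = int(np.argmin(vals))
        if vals[j] < best_val:
            best_val = vals[j]
            best = cand[j]
    return float(best_val)


def _kabsch(A, B):
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    U, s, Vt = np.linalg.svd(A0.T @ B0)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, B.mean(axis=0) - R @ A.mean(axis=0)


def exhaustive_gdt(A, B, cutoffs=(1.0, 2.0, 4.0, 8.0)) -> float:
    """GDT-TS by enumerating every residue subset of size >= 3 as a
    superposition seed (feasible only for N <= ~10)."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    n = A.shape[0]
    seeds = []
    for r in range(3, n + 1):
        seeds.extend(itertools.combinations(range(n), r))
    fracs = []
    for cutoff in cutoffs:
        best = 0
        for seed in seeds:
            idx = np.array(seed)
            R, t = _kabsch(A[idx], B[idx])
            moved = A @ R.T + t
            within = int(np.sum(np.linalg.norm(moved - B, axis=1) <= cutoff))
            best = max(best, within)
        fracs.append(best / n)
    return float(np.mean(fracs))


def random_rigid_motion(rng: np.random.Generator):
    """A uniform-ish random proper rotation and translation."""
    M = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(M)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=10.0, size=3)
    return Q, t
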