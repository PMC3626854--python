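"""Synthetic decoy sets with known ground truth.

Real decoy sets from fragment-assembly predictors are multimodal: most
candidates pile up near a handful of low-energy basins, one of which
(hopefully) surrounds the correct fold, with a diffuse background of
misfolded outliers.  This module emulates that statistical structure at
desk scale — a protein-like Cα random walk as the "native", several
coordinate-space clusters at controlled RMSD offsets from it, Gaussian
within-cluster spread, far outliers, and pseudo-energies that increase
with distance to native plus noise — so the selection pipeline can be
exercised and scored against known labels without any downloads.

It makes no claim of physical realism (no secondary structure, side chains
or excluded-volume packing beyond a simple clash filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import DecoySet, Structure, write_pdb_calpha
from .metrics import ca_rmsd

#: Cα–Cα virtual bond length in Å.
BOND_LENGTH = 3.8
#: Minimum allowed distance between non-adjacent Cα atoms in Å.
MIN_NONADJ_DIST = 3.0


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic decoy set.

    ``cluster_center_rmsd[k]`` is the target Cα RMSD (Å) from the native to
    cluster k's centre; ``within_cluster_sigma`` the isotropic per-coordinate
    spread of members around their centre; ``outlier_fraction`` adds
    ``round(f · Σ sizes)`` decoys at >= 8 Å from the native.  Energies are
    ``energy_slope · RMSD-to-native + N(0, energy_noise_sigma)``, negated
    when ``invert_energy`` is set (an adversarially wrong scoring function).
    The default noise (2.0 energy units against an RMSD spread of a few Å)
    gives an energy–RMSD correlation of roughly 0.6–0.8 — a reasonably good
    but imperfect scoring function, as real decoy-set funnels are; a much
    smaller noise would make the energy-only baseline an implausible oracle.
    The default recipe keeps at least one cluster centred below 4 Å so the
    set satisfies the standard inclusion rule (some decoy within 4 Å of
    native).
    """

    n_res: int = 40
    cluster_sizes: tuple = (150, 80, 50)
    cluster_center_rmsd: tuple = (2.0, 5.0, 8.0)
    within_cluster_sigma: float = 0.8
    outlier_fraction: float = 0.1
    energy_slope: float = 1.0
    energy_noise_sigma: float = 2.0
    invert_energy: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.cluster_sizes) != len(self.cluster_center_rmsd):
            raise ValueError("cluster_sizes and cluster_center_rmsd must align")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be positive")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must be in [0, 1)")

    @property
    def n_decoys(self) -> int:
        base = sum(self.cluster_sizes)
        return base + int(round(self.outlier_fraction * base))


def generate_native(n_res: int, rng: np.random.Generator, max_attempts: int = 200) -> Structure:
    """Protein-like Cα trace: fixed 3.8 Å virtual bonds, pseudo-bond angles
    in the 85–145° range, random torsions, and no two non-adjacent Cα atoms
    closer than 3.0 Å (rejection sampling with bounded restarts)."""
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    for _ in range(max_attempts):
        coords = _try_chain(n_res, rng)
        if coords is not None:
            return Structure(id="native", coords=coords)
    raise RuntimeError(f"failed to generate a clash-free chain in {max_attempts} attempts")


def _try_chain(n_res: int, rng: np.random.Generator) -> Optional[np.ndarray]:
    coords = np.zeros((n_res, 3))
    coords[1] = (BOND_LENGTH, 0.0, 0.0)
    for i in range(2, n_res):
        placed = False
        for _ in range(30):
            theta = np.deg2rad(rng.uniform(85.0, 145.0))  # pseudo-bond angle
            phi = rng.uniform(-np.pi, np.pi)  # pseudo-torsion
            new = _place_next(coords[:i], theta, phi)
            d = np.linalg.norm(coords[: i - 1] - new, axis=1)
            if np.all(d >= MIN_NONADJ_DIST):
                coords[i] = new
                placed = True
                break
        if not placed:
            return None
    return coords


def _place_next(prev: np.ndarray, theta: float, phi: float) -> np.ndarray:
    """Extend the chain by one Cα using a local frame on the last bond."""
    b = prev[-1] - prev[-2]
    b /= np.linalg.norm(b)
    # any vector not parallel to b
    ref = np.array([1.0, 0.0, 0.0]) if abs(b[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(b, ref)
    u /= np.linalg.norm(u)
    v = np.cross(b, u)
    direction = (
        -np.cos(theta) * b + np.sin(theta) * (np.cos(phi) * u + np.sin(phi) * v)
    )
    return prev[-1] + BOND_LENGTH * direction


def _calibrated_perturbation(
    native: np.ndarray,
    target_rmsd: float,
    rng: np.random.Generator,
    tol: float = 0.05,
    max_iter: int = 60,
) -> np.ndarray:
    """Native + scaled Gaussian noise with Kabsch RMSD to native ≈ target.

    The noise direction is drawn once; the scale is found by bisection,
    since superposition removes part of the raw displacement and the
    scale→RMSD map has no closed form but is monotone.
    """
    noise = rng.normal(size=native.shape)
    lo, hi = 0.0, max(4.0 * target_rmsd, 1.0)
    while ca_rmsd(native, native + hi * noise) < target_rmsd:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("calibration failed to bracket the target RMSD")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = ca_rmsd(native, native + mid * noise)
        if abs(r - target_rmsd) <= tol:
            return native + mid * noise
        if r < target_rmsd:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(f"calibration did not converge to {target_rmsd} Å")


def generate_decoy_set(spec: SyntheticSpec) -> tuple[DecoySet, np.ndarray]:
    """Generate a labelled decoy set per ``spec``.

    Returns ``(decoy_set, labels)`` where ``labels[j]`` is the ground-truth
    cluster index of decoy j (−1 for outliers).  The decoy set carries the
    native and per-decoy energies.
    """
    rng = np.random.default_rng(spec.seed)
    native = generate_native(spec.n_res, rng)

    coords: list[np.ndarray] = []
    labels: list[int] = []
    for k, (size, offset) in enumerate(zip(spec.cluster_sizes, spec.cluster_center_rmsd)):
        center = _calibrated_perturbation(native.coords, offset, rng)
        for _ in range(size):
            coords.append(center + rng.normal(scale=spec.within_cluster_sigma, size=center.shape))
            labels.append(k)
    n_out = spec.n_decoys - sum(spec.cluster_sizes)
    for _ in range(n_out):
        target = rng.uniform(8.0, 16.0)
        coords.append(_calibrated_perturbation(native.coords, target, rng))
        labels.append(-1)

    width = len(str(len(coords)))
    structures = []
    for j, xyz in enumerate(coords):
        rmsd_nat = ca_rmsd(native.coords, xyz)
        noise = rng.normal(scale=spec.energy_noise_sigma) if spec.energy_noise_sigma > 0 else 0.0
        energy = spec.energy_slope * rmsd_nat + noise
        if spec.invert_energy:
            energy = -energy
        structures.append(
            Structure(id=f"d{j:0{width}d}", coords=xyz, energy=float(energy))
        )
    dset = DecoySet(structures=structures, native=native, labels=np.array(labels))
    return dset, np.array(labels)


def write_fixture(decoy_set: DecoySet, directory, labels: Optional[np.ndarray] = None) -> None:
    """Write a decoy set as an on-disk fixture that round-trips through
    :func:`hsforest.io.read_decoy_set`: one PDB per decoy, ``energies.tsv``,
    ``native.pdb`` and (if labels given) ``labels.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    decoy_dir = directory / "decoys"
    decoy_dir.mkdir(exist_ok=True)
    for s in decoy_set.structures:
        write_pdb_calpha(s, decoy_dir / f"{s.id}.pdb")
    if decoy_set.native is not None:
        write_pdb_calpha(decoy_set.native, directory / "native.pdb")
    energies = decoy_set.energies()
    if energies is not None:
        with open(directory / "energies.tsv", "w") as fh:
            fh.write("# decoy-id energy\n")
            for s, e in zip(decoy_set.structures, energies):
                fh.write(f"{s.id}\t{e:.6f}\n")
    if labels is None:
        labels = decoy_set.labels
    if labels is not None:
        with open(directory / "labels.tsv", "w") as fh:
            fh.write("# decoy-id cluster (-1 = outlier)\n")
            for s, lab in zip(decoy_set.structures, labels):
                fh.write(f"{s.id}\t{int(lab)}\n")
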