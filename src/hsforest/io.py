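"""Reading decoy structures and energy tables; writing selection reports.

Decoys are candidate 3D structures produced by an ab initio structure
prediction program.  Only the Cα trace is retained: the clustering distance
is the Cα RMSD, and parsing anything more would multiply memory for no
benefit on sets of tens of thousands of decoys.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)


@dataclass
class Structure:
    """One decoy's Cα trace.

    Attributes
    ----------
    id : str
        Decoy identifier, typically the filename stem.
    coords : (N, 3) float array
        Cα coordinates in Å, in residue order as read from the file.
    energy : float or None
        Scoring-function value, lower = better.  Optional: selection falls
        back to the pivot-based consensus pseudo-energy when absent.
    """

    id: str
    coords: np.ndarray
    energy: Optional[float] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"{self.id}: coords must be (N, 3)")
        if len(self.coords) < 3:
            raise ValueError(f"{self.id}: structure has {len(self.coords)} residues, need >= 3")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class DecoySet:
    """Homogeneous collection of equal-length decoys, with optional native.

    The native (experimentally determined) structure is used for evaluation
    only and is never a member of ``structures``.
    """

    structures: list[Structure]
    native: Optional[Structure] = None
    labels: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.structures) < 2:
            raise ValueError("a decoy set needs at least 2 decoys")
        lengths = {len(s) for s in self.structures}
        if len(lengths) != 1:
            raise ValueError(f"decoys have mixed lengths: {sorted(lengths)}")
        ids = [s.id for s in self.structures]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise ValueError(f"duplicate decoy ids: {dup}")
        if self.native is not None and len(self.native) != self.length:
            raise ValueError(
                f"native length {len(self.native)} != decoy length {self.length}"
            )

    @property
    def length(self) -> int:
        return len(self.structures[0])

    @property
    def n(self) -> int:
        return len(self.structures)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.structures]

    def coords_array(self) -> np.ndarray:
        """All decoy coordinates stacked as (N, L, 3)."""
        return np.stack([s.coords for s in self.structures])

    def energies(self) -> Optional[np.ndarray]:
        """Energy vector aligned with ``structures``; None if no decoy has one.
        Decoys without an energy get NaN."""
        vals = [s.energy for s in self.structures]
        if all(v is None for v in vals):
            return None
        return np.array([np.nan if v is None else float(v) for v in vals])


def read_pdb_calpha(path) -> Structure:
    """Read one decoy: one Cα per residue, first model, first altloc.

    Raises ``ValueError`` naming the residue if any amino-acid residue lacks
    a Cα atom, or if the file contains no ATOM records.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    models = list(parser.get_structure(path.stem, str(path)).get_models())
    if not models:
        raise ValueError(f"{path.name}: no ATOM records")
    model = models[0]
    coords = []
    for chain in model:
        for res in chain:
            if res.id[0] != " ":  # skip HETATM / water
                continue
            if "CA" not in res:
                raise ValueError(
                    f"{path.name}: residue {chain.id}/{res.id[1]} has no CA atom"
                )
            atom = res["CA"]
            if atom.is_disordered():
                # first alternate location (blank or 'A'), not highest occupancy
                alt = sorted(atom.disordered_get_id_list())[0]
                atom = atom.disordered_get(alt)
            coords.append(atom.get_coord())
    if not coords:
        raise ValueError(f"{path.name}: no ATOM records")
    return Structure(id=path.stem, coords=np.array(coords, dtype=float))


def read_energy_table(path) -> dict[str, float]:
    """Parse a two-column whitespace-delimited ``id energy`` table.

    Lines starting with ``#`` are comments; a duplicated id keeps the last
    value (with a warning); a non-numeric energy raises with the line number.
    """
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            key, val = parts
            try:
                energy = float(val)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric energy {val!r}") from None
            if key in out:
                logger.warning("%s: line %d: duplicate id %r, last value wins", path, lineno, key)
            out[key] = energy
    return out


def read_decoy_set(directory, energy_table=None, native=None) -> DecoySet:
    """Load all ``*.pdb`` decoys in a directory into a :class:`DecoySet`.

    Decoys whose length differs from the modal length are excluded with a
    logged warning.  Energies are joined by filename stem when a table is
    given; a table id matching no decoy triggers a warning.  The native file,
    if it lives inside the directory, is not counted as a decoy.
    """
    directory = Path(directory)
    native_struct = read_pdb_calpha(native) if native is not None else None
    native_path = Path(native).resolve() if native is not None else None

    paths = sorted(p for p in directory.glob("*.pdb") if p.resolve() != native_path)
    if len(paths) < 2:
        raise ValueError(f"{directory}: found {len(paths)} decoys, need >= 2")
    structures = [read_pdb_calpha(p) for p in paths]

    modal_length = Counter(len(s) for s in structures).most_common(1)[0][0]
    kept = []
    for s in structures:
        if len(s) == modal_length:
            kept.append(s)
        else:
            logger.warning(
                "excluding decoy %s: length %d != modal length %d", s.id, len(s), modal_length
            )
    if len(kept) < 2:
        raise ValueError(f"{directory}: fewer than 2 decoys after length filtering")

    if energy_table is not None:
        table = read_energy_table(energy_table)
        ids = {s.id for s in kept}
        for key in table:
            if key not in ids:
                logger.warning("energy table id %r matches no decoy", key)
        for s in kept:
            if s.id in table:
                s.energy = table[s.id]

    if native_struct is not None and len(native_struct) != modal_length:
        raise ValueError(
            f"native length {len(native_struct)} != decoy length {modal_length}"
        )
    return DecoySet(structures=kept, native=native_struct)


def write_pdb_calpha(structure: Structure, path) -> None:
    """Write a Cα-only trace as fixed-width PDB v3.3 ATOM records.

    Minimal fixture writer (3-decimal coordinate precision, chain A,
    sequential residue numbers); for synthetic decoys and tests only.
    """
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(structure.coords, start=1):
            fh.write(
                f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("TER\nEND\n")


def write_selection_report(result, path) -> None:
    """Write a selection result as a deterministic JSON report.

    The payload is byte-identical across re-runs with the same seed and
    inputs (keys sorted, no timestamp).  A human-readable summary is
    available from ``result.summary()``.
    """
    payload = result.to_dict()
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
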