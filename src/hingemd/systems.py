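"""In-memory containers for structures and trajectories.

The whole analysis pipeline consumes two containers: a
:class:`MolecularSystem` (the static topology: atom identities plus one
reference coordinate set) and a :class:`Trajectory` (an ordered stack of
coordinate frames over the same atoms, with frame times in nanoseconds).
Coordinates are ångström throughout; residue numbering is 1-based as in PDB
files; insertion codes are part of the residue identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import DomainError, TopologyError

# Standard atomic masses (amu) keyed by upper-case element symbol.  Entries
# cover everything the analyses meet: protein heavy atoms, hydrogens, common
# ions and halogens.  Unknown elements fall back to carbon's mass with a
# warning from callers that care.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "CU": 63.546, "MN": 54.938, "CD": 112.414, "SE": 78.971,
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.

    ``residue_icode`` carries the PDB insertion code (empty string when
    absent); together with ``chain_id`` and ``residue_number`` it forms the
    residue key used everywhere downstream.
    """

    atom_id: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    is_hetero: bool = False
    residue_icode: str = ""

    def __post_init__(self) -> None:
        if self.atom_id <= 0:
            raise ValueError(f"atom_id must be positive, got {self.atom_id}")
        if not self.element:
            raise ValueError("element must be non-empty")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain_id, residue_number, insertion code) — unique residue id."""
        return (self.chain_id, self.residue_number, self.residue_icode)

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element.upper(), ATOMIC_MASSES["C"])


class MolecularSystem:
    """Atoms plus one reference coordinate set.

    Parameters
    ----------
    atoms
        Ordered atom records; ``atom_id`` must be unique.
    reference_coordinates
        (n_atoms, 3) array in Å; finite.
    """

    def __init__(self, atoms: Sequence[AtomRecord],
                 reference_coordinates: np.ndarray) -> None:
        coords = np.asarray(reference_coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise DomainError(
                f"reference coordinates must be (n, 3), got {coords.shape}")
        if len(atoms) != coords.shape[0]:
            raise TopologyError(
                f"{len(atoms)} atoms but {coords.shape[0]} coordinate rows")
        if not np.all(np.isfinite(coords)):
            raise DomainError("reference coordinates contain non-finite values")
        ids = [a.atom_id for a in atoms]
        if len(set(ids)) != len(ids):
            raise TopologyError("atom_id values are not unique")
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        self.reference_coordinates = coords

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> frozenset[str]:
        return frozenset(a.chain_id for a in self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Residue key of every atom, in atom order."""
        return [a.residue_key for a in self.atoms]

    def atoms_by_residue(self) -> dict[tuple[str, int, str], list[int]]:
        """Map residue key -> atom indices, preserving atom order."""
        out: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_key, []).append(i)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<MolecularSystem {self.n_atoms} atoms, "
                f"{len(set(self.residue_keys()))} residues, "
                f"chains {sorted(self.chains)}>")


@dataclass
class Trajectory:
    """Ordered coordinate frames (Å) over a fixed atom set, with times (ns)."""

    system: MolecularSystem
    frames: np.ndarray = field(repr=False)
    frame_times: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise DomainError(
                f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise DomainError("a trajectory needs at least one frame")
        if self.frames.shape[1] != self.system.n_atoms:
            raise TopologyError(
                f"frames carry {self.frames.shape[1]} atoms but the system "
                f"has {self.system.n_atoms}")
        if self.frame_times.shape != (self.frames.shape[0],):
            raise DomainError("frame_times length must equal frame count")
        if np.any(np.diff(self.frame_times) < 0):
            raise DomainError("frame_times must be monotone non-decreasing")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]
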