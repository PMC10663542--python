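"""Shared fixtures: small hand-built systems and random-system factories."""

from __future__ import annotations

import numpy as np
import pytest

from hingemd.systems import AtomRecord, MolecularSystem, Trajectory

# A hand-written two-residue, two-chain PDB fixture (10 atoms).
TWO_RESIDUE_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   ALA B   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  ALA B   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      7  C   ALA B   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      8  O   ALA B   2       6.052   1.593   0.000  1.00  0.00           O
ATOM      9  CB  ALA B   2       3.601   3.655   1.232  1.00  0.00           C
HETATM   10 ZN    ZN B  99       8.000   8.000   8.000  1.00  0.00          ZN
END
"""


@pytest.fixture
def two_residue_pdb(tmp_path):
    path = tmp_path / "two_residue.pdb"
    path.write_text(TWO_RESIDUE_PDB)
    return path


def make_random_system(rng: np.random.Generator, n_atoms: int = 60
                       ) -> MolecularSystem:
    """A random multi-chain system for selection / geometry property tests."""
    chains = ["A", "B", "C"]
    resnames = ["GLY", "ALA", "SER", "LYS", "ASP"]
    names = ["N", "CA", "C", "O", "CB", "H"]
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "H": "H"}
    atoms = []
    for i in range(n_atoms):
        name = names[int(rng.integers(len(names)))]
        atoms.append(AtomRecord(
            atom_id=i + 1,
            atom_name=name,
            element=elements[name],
            residue_name=resnames[int(rng.integers(len(resnames)))],
            residue_number=int(rng.integers(1, 30)),
            chain_id=chains[int(rng.integers(len(chains)))],
            is_hetero=bool(rng.random() < 0.1),
        ))
    coords = rng.normal(scale=10.0, size=(n_atoms, 3))
    return MolecularSystem(atoms, coords)


@pytest.fixture
def random_system():
    return make_random_system(np.random.default_rng(42))


def single_atom_system(element: str = "C", n: int = 1,
                       coords: np.ndarray | None = None) -> MolecularSystem:
    atoms = [AtomRecord(i + 1, element, element, "UNK", i + 1, "A")
             for i in range(n)]
    if coords is None:
        coords = np.zeros((n, 3))
    return MolecularSystem(atoms, np.asarray(coords, dtype=float))


def make_trajectory(system: MolecularSystem, frames: np.ndarray,
                    dt: float = 0.1) -> Trajectory:
    frames = np.asarray(frames, dtype=float)
    return Trajectory(system, frames, np.arange(frames.shape[0]) * dt)
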