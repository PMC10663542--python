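"""Geometric primitives: centers of mass, the three-domain hinge angle,
and least-squares (Kabsch) superposition with RMSD.

The hinge angle of a two-lobed protein connected by a hinge region is the
angle at the hinge domain's center of mass (COM) subtended by the COMs of
the two flanking domains.  For the IZUMO1-like architecture those are the
four-helix bundle (4HB), the hinge, and the Ig-like domain; an angle above
the classification threshold (140 deg by default downstream) is called
"straight", below it "boomerang".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .systems import MolecularSystem

__all__ = [
    "DomainDefinition", "RigidTransform", "center_of_mass", "hinge_angle",
    "superpose_rmsd", "kabsch",
]


@dataclass(frozen=True)
class DomainDefinition:
    """A named structural domain as closed residue-number intervals per chain.

    ``residue_ranges`` maps a chain id to a list of closed (lo, hi)
    residue-number intervals.  Intervals within one chain must be non-empty
    and non-overlapping.
    """

    label: str
    residue_ranges: dict[str, tuple[tuple[int, int], ...]]

    def __post_init__(self) -> None:
        norm = {}
        for chain, ranges in self.residue_ranges.items():
            ranges = tuple(tuple(r) for r in ranges)
            for lo, hi in ranges:
                if hi < lo:
                    raise DomainError(
                        f"domain {self.label!r}: empty interval {lo}-{hi}")
            srt = sorted(ranges)
            for (a_lo, a_hi), (b_lo, b_hi) in zip(srt, srt[1:]):
                if b_lo <= a_hi:
                    raise DomainError(
                        f"domain {self.label!r}: overlapping intervals on "
                        f"chain {chain!r}")
            norm[chain] = ranges
        object.__setattr__(self, "residue_ranges", norm)

    def atom_indices(self, system: MolecularSystem,
                     heavy_only: bool = True,
                     ca_only: bool = False) -> np.ndarray:
        """Atom indices belonging to the domain, in atom order."""
        out = []
        for i, a in enumerate(system.atoms):
            ranges = self.residue_ranges.get(a.chain_id)
            if ranges is None:
                continue
            if not any(lo <= a.residue_number <= hi for lo, hi in ranges):
                continue
            if ca_only and a.atom_name.upper() != "CA":
                continue
            if heavy_only and a.element.upper() == "H":
                continue
            out.append(i)
        return np.array(out, dtype=int)

    def overlaps(self, other: "DomainDefinition") -> bool:
        for chain, ranges in self.residue_ranges.items():
            for lo, hi in ranges:
                for olo, ohi in other.residue_ranges.get(chain, ()):
                    if lo <= ohi and olo <= hi:
                        return True
        return False


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise DomainError("rotation must be 3x3 and translation length 3")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise DomainError("rotation determinant must be +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def center_of_mass(coords: np.ndarray, indices: np.ndarray,
                   weights: np.ndarray | str = "unit") -> np.ndarray:
    """Weighted mean position of the selected atoms (Å).

    ``weights`` may be an explicit per-selected-atom array, ``"unit"``
    (centroid), or a per-atom mass array indexed by ``indices``.
    """
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise DomainError("center of mass of an empty atom set")
    pts = np.asarray(coords)[indices]
    if isinstance(weights, str):
        if weights != "unit":
            raise DomainError(f"unknown weighting mode {weights!r}")
        w = np.ones(len(indices))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] == np.asarray(coords).shape[0]:
            w = w[indices]
        if w.shape[0] != len(indices):
            raise DomainError("weight count does not match selection")
    return (pts * w[:, None]).sum(axis=0) / w.sum()


def hinge_angle(coords: np.ndarray, system: MolecularSystem,
                domains: tuple[DomainDefinition, DomainDefinition,
                               DomainDefinition],
                mass_weighted: bool = True,
                ca_only: bool = False) -> float:
    """Hinge angle (degrees, [0, 180]) of one coordinate frame.

    ``domains`` is (first lobe, hinge, second lobe) — the middle domain is
    the vertex.  COMs use atomic masses over heavy atoms by default
    (hydrogens included when present); ``ca_only`` restricts to Cα atoms.
    Raises :class:`DomainError` for empty domains, overlapping domains, or
    coincident COMs (arm shorter than 1e-9 Å).
    """
    if len(domains) != 3:
        raise DomainError("hinge_angle needs exactly three domains")
    for a in range(3):
        for b in range(a + 1, 3):
            if domains[a].overlaps(domains[b]):
                raise DomainError(
                    f"hinge domains {domains[a].label!r} and "
                    f"{domains[b].label!r} overlap")
    coms = []
    masses = system.masses
    for dom in domains:
        idx = dom.atom_indices(system, heavy_only=True, ca_only=ca_only)
        if idx.size == 0:
            raise DomainError(f"domain {dom.label!r} selects no atoms")
        w = masses if mass_weighted else "unit"
        coms.append(center_of_mass(coords, idx, w))
    v1 = coms[0] - coms[1]
    v2 = coms[2] - coms[1]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise DomainError("degenerate geometry: coincident domain COMs")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares proper rotation+translation mapping mobile onto
    reference (both (n, 3), row-matched)."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return RigidTransform(R, t)


def superpose_rmsd(mobile: np.ndarray, reference: np.ndarray,
                   fit_indices: np.ndarray,
                   rmsd_indices: np.ndarray | None = None
                   ) -> tuple[RigidTransform, float]:
    """Superpose ``mobile`` onto ``reference`` on ``fit_indices`` and report
    the RMSD over ``rmsd_indices`` (defaults to the fit set) after the fit.

    Index sets address the same atoms in both coordinate arrays (1:1).
    Needs at least three non-collinear fit atoms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise DomainError("mobile and reference must have equal shapes")
    fit = np.asarray(fit_indices, dtype=int)
    if fit.size < 3:
        raise DomainError("superposition needs at least 3 fit atoms")
    pts = mobile[fit] - mobile[fit].mean(axis=0)
    # collinearity check: second singular value ~ 0
    if np.linalg.svd(pts, compute_uv=False)[1] < 1e-9:
        raise DomainError("fit atoms are collinear")
    transform = kabsch(mobile[fit], reference[fit])
    rid = fit if rmsd_indices is None else np.asarray(rmsd_indices, dtype=int)
    moved = transform.apply(mobile[rid])
    rmsd = float(np.sqrt(((moved - reference[rid]) ** 2).sum(axis=1).mean()))
    return transform, rmsd
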