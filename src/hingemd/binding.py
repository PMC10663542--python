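"""Ligand and ion binding-event detection along trajectories.

Tracks a ligand's approach to a receptor (per-frame minimum heavy-atom
distance and closest receptor residue), its first contact, its per-frame
state (free / surface / pocket-bound) with an insertion-depth series, and
the residence of a single-atom ion at a coordination site.

Insertion depth is operationalized as the buried fraction of the ligand's
solvent-accessible surface when complexed with the receptor,

    depth = 1 − SASA(ligand in complex) / SASA(ligand alone),

a relative measure in [0, 1]: 0 at infinite separation, approaching 1 for
a fully enclosed ligand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError
from .sasa import shrake_rupley_sasa, vdw_radii
from .systems import Trajectory

__all__ = ["BindingEvent", "IonSite", "IonTracking",
           "ligand_distance_timeline", "detect_first_contact",
           "classify_ligand_state", "ion_site_tracking",
           "majority_filter"]

STATE_FREE, STATE_SURFACE, STATE_POCKET = 0, 1, 2
STATE_LABELS = ("free", "surface", "pocket-bound")


@dataclass
class BindingEvent:
    """Ligand binding timeline over one trajectory."""

    ligand_id: tuple[str, int, str]
    first_contact_frame: int | None
    first_contact_residue: tuple[str, int, str] | None
    bound_intervals: tuple[tuple[int, int], ...]
    state_series: np.ndarray            # per-frame STATE_* codes (smoothed)
    raw_state_series: np.ndarray        # before the 3-frame majority filter
    insertion_depth: np.ndarray


@dataclass(frozen=True)
class IonSite:
    """A coordination site: a set of residues and a binding cutoff."""

    site_id: str
    coordinating_residues: tuple[tuple[str, int, str], ...]
    bound_cutoff: float = 3.0

    def __post_init__(self) -> None:
        if not self.coordinating_residues:
            raise ConfigError(f"ion site {self.site_id!r} has no residues")
        if self.bound_cutoff <= 0:
            raise ConfigError("bound_cutoff must be positive")


@dataclass
class IonTracking:
    site_id: str
    bound: np.ndarray                # per-frame bool
    coordination_count: np.ndarray   # per-frame residue count within cutoff
    unbinding_frame: int | None      # first frame after which never bound
    ever_bound: bool


def ligand_distance_timeline(trajectory: Trajectory, ligand: np.ndarray,
                             receptor: np.ndarray
                             ) -> tuple[np.ndarray, list]:
    """Per-frame minimum heavy-atom distance (Å) between ligand and
    receptor, plus the closest receptor residue per frame.

    The closest residue is that of the arg-min receptor atom; distance ties
    resolve to the lower residue number.
    """
    ligand = np.asarray(ligand, dtype=int)
    receptor = np.asarray(receptor, dtype=int)
    if ligand.size == 0 or receptor.size == 0:
        raise DomainError("ligand and receptor selections must be non-empty")
    if np.intersect1d(ligand, receptor).size:
        raise DomainError("ligand and receptor selections overlap")
    atoms = trajectory.system.atoms
    heavy_lig = ligand[[atoms[i].element.upper() != "H" for i in ligand]]
    heavy_rec = receptor[[atoms[i].element.upper() != "H" for i in receptor]]
    if heavy_lig.size == 0 or heavy_rec.size == 0:
        raise DomainError("selections contain no heavy atoms")
    rec_res = [atoms[i].residue_key for i in heavy_rec]
    min_dist = np.empty(trajectory.n_frames)
    closest: list[tuple[str, int, str]] = []
    for f in range(trajectory.n_frames):
        coords = trajectory.frames[f]
        d = np.linalg.norm(coords[heavy_lig][:, None, :]
                           - coords[heavy_rec][None, :, :], axis=2)
        per_atom = d.min(axis=0)
        dmin = float(per_atom.min())
        min_dist[f] = dmin
        ties = np.flatnonzero(per_atom <= dmin + 1e-12)
        res = min((rec_res[t] for t in ties), key=lambda r: (r[1], r[0], r[2]))
        closest.append(res)
    return min_dist, closest


def detect_first_contact(min_distances: np.ndarray,
                         closest_residues: list | None = None,
                         contact_cutoff: float = 4.0
                         ) -> tuple[int | None, tuple | None]:
    """Earliest frame whose minimum distance is at or below the cutoff,
    with the closest residue at that frame (``None``/``None`` if never)."""
    if contact_cutoff <= 0:
        raise ConfigError("contact_cutoff must be positive")
    hits = np.flatnonzero(np.asarray(min_distances) <= contact_cutoff)
    if hits.size == 0:
        return None, None
    frame = int(hits[0])
    residue = closest_residues[frame] if closest_residues is not None else None
    return frame, residue


def majority_filter(series: np.ndarray, window: int = 3) -> np.ndarray:
    """Sliding-window majority vote over a label series (odd window;
    edges use the shrunken window)."""
    series = np.asarray(series)
    if window <= 1:
        return series.copy()
    half = window // 2
    out = series.copy()
    for i in range(series.size):
        lo, hi = max(0, i - half), min(series.size, i + half + 1)
        vals, counts = np.unique(series[lo:hi], return_counts=True)
        out[i] = vals[np.argmax(counts)]
    return out


def classify_ligand_state(trajectory: Trajectory, ligand: np.ndarray,
                          pocket_residues: list[tuple[str, int, str]],
                          receptor: np.ndarray | None = None,
                          contact_cutoff: float = 4.0,
                          buried_threshold: float = 0.4,
                          smoothing_window: int = 3,
                          sasa_points: int = 240) -> BindingEvent:
    """Per-frame ligand state, insertion depth and bound intervals.

    A frame is *pocket-bound* when the ligand has heavy-atom contacts
    (≤ ``contact_cutoff``) with at least three distinct pocket residues and
    its buried SASA fraction is at least ``buried_threshold``; *surface*
    when it touches the receptor at all but is not pocket-bound; *free*
    otherwise.  The bound/unbound series is smoothed with a 3-frame
    majority filter before interval extraction; the raw series is kept on
    the returned event.

    ``receptor`` defaults to all non-ligand heavy atoms.  ``sasa_points``
    trades quadrature accuracy for speed in the per-frame depth series.
    """
    if not pocket_residues:
        raise DomainError("pocket residue set must be non-empty")
    if contact_cutoff <= 0:
        raise ConfigError("contact_cutoff must be positive")
    ligand = np.asarray(ligand, dtype=int)
    atoms = trajectory.system.atoms
    if receptor is None:
        receptor = np.setdiff1d(np.arange(trajectory.n_atoms), ligand)
    receptor = np.asarray(receptor, dtype=int)
    heavy = np.array([a.element.upper() != "H" for a in atoms])
    lig = ligand[heavy[ligand]]
    rec = receptor[heavy[receptor]]
    if lig.size == 0 or rec.size == 0:
        raise DomainError("ligand/receptor selections contain no heavy atoms")
    pocket_keys = {tuple(p) for p in pocket_residues}
    rec_keys = [atoms[i].residue_key for i in rec]
    radii = vdw_radii(trajectory.system)

    n = trajectory.n_frames
    raw = np.empty(n, dtype=np.int8)
    depth = np.empty(n)
    both = np.concatenate([lig, rec])
    lig_slice = slice(0, lig.size)
    for f in range(n):
        coords = trajectory.frames[f]
        d = np.linalg.norm(coords[lig][:, None, :] - coords[rec][None, :, :],
                           axis=2)
        touch = d.min(axis=0) <= contact_cutoff
        touched_res = {rec_keys[i] for i in np.flatnonzero(touch)}
        sasa_alone = shrake_rupley_sasa(coords[lig], radii[lig],
                                        n_points=sasa_points).sum()
        sasa_complex = shrake_rupley_sasa(coords[both], radii[both],
                                          n_points=sasa_points)[lig_slice].sum()
        depth[f] = 0.0 if sasa_alone <= 0 else \
            float(np.clip(1.0 - sasa_complex / sasa_alone, 0.0, 1.0))
        n_pocket = len(touched_res & pocket_keys)
        if n_pocket >= 3 and depth[f] >= buried_threshold:
            raw[f] = STATE_POCKET
        elif touched_res:
            raw[f] = STATE_SURFACE
        else:
            raw[f] = STATE_FREE
    smooth = majority_filter(raw, smoothing_window)
    intervals: list[tuple[int, int]] = []
    start = None
    for i, s in enumerate(smooth):
        if s == STATE_POCKET and start is None:
            start = i
        elif s != STATE_POCKET and start is not None:
            intervals.append((start, i - 1))
            start = None
    if start is not None:
        intervals.append((start, n - 1))
    min_dist, closest = ligand_distance_timeline(trajectory, lig, rec)
    frame, residue = detect_first_contact(min_dist, closest, contact_cutoff)
    lig_atom = atoms[lig[0]]
    lig_id = (lig_atom.chain_id, lig_atom.residue_number,
              lig_atom.residue_name)
    if residue is not None:
        rk = residue
        res_atoms = trajectory.system.atoms_by_residue()[rk]
        residue = (rk[0], rk[1], atoms[res_atoms[0]].residue_name)
    return BindingEvent(
        ligand_id=lig_id,
        first_contact_frame=frame,
        first_contact_residue=residue,
        bound_intervals=tuple(intervals),
        state_series=smooth,
        raw_state_series=raw,
        insertion_depth=depth,
    )


def ion_site_tracking(trajectory: Trajectory, ion: np.ndarray, site: IonSite,
                      coord_cutoff: float | None = None) -> IonTracking:
    """Track a single-atom ion at a coordination site.

    ``coordination_count`` is the number of distinct site residues with any
    heavy atom within the cutoff of the ion; the ion is bound while the
    count is ≥ 1.  The unbinding frame is the first frame after which the
    ion is never bound again; it is ``None`` when the ion stays bound to
    the end or was never bound at all (see ``ever_bound``).
    """
    ion = np.asarray(ion, dtype=int)
    if ion.size != 1:
        raise DomainError("ion selection must contain exactly one atom")
    cutoff = site.bound_cutoff if coord_cutoff is None else coord_cutoff
    if cutoff <= 0:
        raise ConfigError("coordination cutoff must be positive")
    by_res = trajectory.system.atoms_by_residue()
    atoms = trajectory.system.atoms
    site_atoms: dict[tuple, np.ndarray] = {}
    for key in site.coordinating_residues:
        key = tuple(key)
        if key not in by_res:
            raise DomainError(f"site residue {key} not in the topology")
        idx = np.array([i for i in by_res[key]
                        if atoms[i].element.upper() != "H"])
        site_atoms[key] = idx
    n = trajectory.n_frames
    counts = np.zeros(n, dtype=int)
    ion_idx = int(ion[0])
    for f in range(n):
        coords = trajectory.frames[f]
        p = coords[ion_idx]
        counts[f] = sum(
            bool(np.any(np.linalg.norm(coords[idx] - p, axis=1) <= cutoff))
            for idx in site_atoms.values())
    bound = counts >= 1
    ever = bool(bound.any())
    unbind: int | None = None
    if ever and not bound[-1]:
        last = int(np.flatnonzero(bound)[-1])
        unbind = last + 1
    return IonTracking(site.site_id, bound, counts, unbind, ever)
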