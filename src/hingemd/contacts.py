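"""Non-covalent interaction detection, scoring and lifetime statistics.

Residue-residue (and residue-ligand) interactions are detected per frame by
geometric criteria, scored with a smooth distance kernel, and aggregated
into per-pair records with mean scores, lifetime fractions and contact
episodes, then combined across replicas into a consensus network.

Geometric criteria
------------------
hydrogen bond
    With hydrogens present: H···acceptor distance ≤ 2.5 Å and
    donor–H–acceptor angle ≥ 120°.  Without hydrogens (crystal files):
    donor–acceptor heavy-atom distance ≤ 3.5 Å (fallback mode, logged).
salt bridge
    Any cationic-group heavy atom within 4.0 Å of an anionic-group heavy
    atom.
π-stacking
    Aromatic ring centroids within 5.5 Å with inter-normal angle ≤ 30°
    (parallel) or in [60°, 90°] (T-shaped).
hydrophobic
    Two hydrophobic carbons of different residues within 4.0 Å.

Contact score
-------------
The per-frame score of a residue pair sums a sigmoidal weight over all
inter-group heavy-atom pairs within 6 Å,

    w(d) = 1 / (1 + exp(5 · (d − 4.0)))          (w(4 Å) = 0.5),

and a pair is retained when its mean score over frames exceeds 1.0
(protein–protein) or 0.1 (protein–ligand).  The kernel is this package's
documented score contract; it is monotone decreasing, smooth, and has its
midpoint at a typical heavy-atom contact distance, so the retention
thresholds behave as published for PyContact-style scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, DomainError
from .systems import MolecularSystem, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "AtomClassMap", "InteractionRecord", "ConsensusNetwork", "TimelineStats",
    "classify_atoms", "detect_hbonds", "detect_contacts_by_class",
    "score_kernel", "score_residue_pairs", "aggregate_timeline",
    "cross_run_consensus", "register_ligand_template",
    "PROTEIN_PROTEIN_THRESHOLD", "PROTEIN_LIGAND_THRESHOLD",
]

PROTEIN_PROTEIN_THRESHOLD = 1.0
PROTEIN_LIGAND_THRESHOLD = 0.1
#: Per-frame presence threshold = retention threshold × this factor.
PRESENCE_FACTOR = 0.5
SCORE_DISTANCE_CUTOFF = 6.0
CLASS_PRECEDENCE = ("hbond", "saltbridge", "pi_stacking", "hydrophobic",
                    "other")

# --------------------------------------------------------------------------
# chemistry lookup (heavy atoms, by residue and atom name)
# --------------------------------------------------------------------------

_BACKBONE_DONOR = {"N"}
_BACKBONE_ACCEPTOR = {"O", "OXT"}

_SIDECHAIN_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"}, "ASN": {"ND2"}, "GLN": {"NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"}, "CYS": {"SG"},
}
_CATIONIC: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2", "CZ"}, "LYS": {"NZ"},
}
_ANIONIC: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
}
_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
}
_HYDROPHOBIC: dict[str, set[str]] = {
    "ALA": {"CB"}, "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"}, "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "CE"}, "PRO": {"CB", "CG", "CD"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "THR": {"CG2"}, "LYS": {"CB", "CG", "CD"}, "ARG": {"CB", "CG"},
    "GLU": {"CB", "CG"}, "GLN": {"CB", "CG"}, "ASP": {"CB"}, "ASN": {"CB"},
    "HIS": {"CB"}, "CYS": {"CB"}, "GLY": set(), "SER": {"CB"},
}
_STANDARD_RESIDUES = set(_HYDROPHOBIC) | {"GLY", "SER"}

#: Registered non-protein residue templates (resname -> class sets).  The
#: toy ligand shipped with the synthetic generators is pre-registered; real
#: ligands (e.g. folate) are registered by the user from their topology.
LIGAND_TEMPLATES: dict[str, dict] = {
    "LIG": {"donors": set(), "acceptors": set(), "cationic": set(),
            "anionic": set(), "rings": (), "hydrophobic": {"C1"}},
    "PKT": {"donors": set(), "acceptors": set(), "cationic": set(),
            "anionic": set(), "rings": (), "hydrophobic": {"CA"}},
}
# the 9-bead hinge molecule's domain residues are plain carbon beads
for _resname in ("FHB", "HNG", "IGL"):
    LIGAND_TEMPLATES[_resname] = {
        "donors": set(), "acceptors": set(), "cationic": set(),
        "anionic": set(), "rings": (),
        "hydrophobic": {"C1", "C2", "C3"}}


def register_ligand_template(resname: str, donors=(), acceptors=(),
                             cationic=(), anionic=(), rings=(),
                             hydrophobic=()) -> None:
    """Register atom-class assignments for a non-protein residue."""
    LIGAND_TEMPLATES[resname.upper()] = {
        "donors": set(donors), "acceptors": set(acceptors),
        "cationic": set(cationic), "anionic": set(anionic),
        "rings": tuple(tuple(r) for r in rings),
        "hydrophobic": set(hydrophobic),
    }


# --------------------------------------------------------------------------
# atom classification
# --------------------------------------------------------------------------


@dataclass
class AtomClassMap:
    """Per-atom interaction classes for one system.

    Boolean arrays are in atom order; ``aromatic_rings`` lists the atom
    index groups of every 5- or 6-membered aromatic ring;
    ``donor_hydrogens`` maps a donor heavy atom to its covalently bonded
    hydrogens (empty when the structure has no hydrogens, in which case
    detectors use heavy-atom fallbacks).
    """

    system: MolecularSystem
    hbond_donor: np.ndarray
    hbond_acceptor: np.ndarray
    cationic: np.ndarray
    anionic: np.ndarray
    hydrophobic: np.ndarray
    aromatic_rings: tuple[np.ndarray, ...]
    donor_hydrogens: dict[int, tuple[int, ...]]

    @property
    def has_hydrogens(self) -> bool:
        return any(self.donor_hydrogens.values())

    @property
    def heavy(self) -> np.ndarray:
        return np.array([a.element.upper() != "H" for a in self.system.atoms])


def classify_atoms(system: MolecularSystem) -> AtomClassMap:
    """Assign interaction classes from residue/atom names.

    Deterministic lookup over the 20 standard amino acids plus registered
    ligand templates; unknown residues get empty classes and a logged
    warning.  Donor hydrogens are identified by a bonding distance below
    1.2 Å in the reference coordinates.
    """
    n = system.n_atoms
    donor = np.zeros(n, dtype=bool)
    acceptor = np.zeros(n, dtype=bool)
    cationic = np.zeros(n, dtype=bool)
    anionic = np.zeros(n, dtype=bool)
    hydrophobic = np.zeros(n, dtype=bool)
    rings: list[np.ndarray] = []
    unknown: set[str] = set()

    for key, idx in system.atoms_by_residue().items():
        resname = system.atoms[idx[0]].residue_name.upper()
        names = {system.atoms[i].atom_name.upper(): i for i in idx}
        if resname in _STANDARD_RESIDUES:
            dset = _BACKBONE_DONOR | _SIDECHAIN_DONORS.get(resname, set())
            if resname == "PRO":
                dset = dset - {"N"}
            aset = _BACKBONE_ACCEPTOR | _SIDECHAIN_ACCEPTORS.get(resname,
                                                                 set())
            cset = _CATIONIC.get(resname, set())
            nset = _ANIONIC.get(resname, set())
            if "OXT" in names:
                nset = nset | {"OXT", "O"}
            hset = _HYDROPHOBIC.get(resname, set())
            ring_defs = _RINGS.get(resname, ())
        elif resname in LIGAND_TEMPLATES:
            tpl = LIGAND_TEMPLATES[resname]
            dset, aset = tpl["donors"], tpl["acceptors"]
            cset, nset = tpl["cationic"], tpl["anionic"]
            hset, ring_defs = tpl["hydrophobic"], tpl["rings"]
        else:
            unknown.add(resname)
            continue
        for name, i in names.items():
            donor[i] = name in dset
            acceptor[i] = name in aset
            cationic[i] = name in cset
            anionic[i] = name in nset
            hydrophobic[i] = name in hset
        for ring in ring_defs:
            members = [names[a] for a in ring if a in names]
            if len(members) == len(ring):
                rings.append(np.array(members, dtype=int))

    if unknown:
        logger.warning("unknown residues left unclassified: %s",
                       ", ".join(sorted(unknown)))

    hydrogens = [i for i, a in enumerate(system.atoms)
                 if a.element.upper() == "H"]
    donor_h: dict[int, tuple[int, ...]] = {}
    if hydrogens:
        coords = system.reference_coordinates
        htree = cKDTree(coords[hydrogens])
        for d in np.flatnonzero(donor):
            near = htree.query_ball_point(coords[d], r=1.2)
            bonded = tuple(hydrogens[j] for j in near
                           if system.atoms[hydrogens[j]].residue_key
                           == system.atoms[d].residue_key)
            if bonded:
                donor_h[d] = bonded
    return AtomClassMap(system, donor, acceptor, cationic, anionic,
                        hydrophobic, tuple(rings), donor_h)


# --------------------------------------------------------------------------
# per-frame detectors
# --------------------------------------------------------------------------


def detect_hbonds(coords: np.ndarray, classes: AtomClassMap,
                  h_dist_cutoff: float = 2.5, angle_cutoff: float = 120.0,
                  heavy_fallback_cutoff: float = 3.5
                  ) -> set[tuple[int, int]]:
    """Hydrogen bonds in one frame as (donor, acceptor) heavy-atom pairs.

    Uses the H-based criterion when the structure carries hydrogens
    (H···A ≤ ``h_dist_cutoff`` and D–H–A ≥ ``angle_cutoff``); otherwise
    falls back to the heavy-atom distance criterion
    (D···A ≤ ``heavy_fallback_cutoff``), logging the fallback once per
    classification.  Donor and acceptor must belong to different residues.
    """
    if min(h_dist_cutoff, angle_cutoff, heavy_fallback_cutoff) <= 0:
        raise ConfigError("hydrogen-bond cutoffs must be positive")
    coords = np.asarray(coords)
    donors = np.flatnonzero(classes.hbond_donor)
    acceptors = np.flatnonzero(classes.hbond_acceptor)
    if donors.size == 0 or acceptors.size == 0:
        return set()
    atoms = classes.system.atoms
    acc_tree = cKDTree(coords[acceptors])
    out: set[tuple[int, int]] = set()
    if classes.has_hydrogens:
        for d in donors:
            for h in classes.donor_hydrogens.get(int(d), ()):
                near = acc_tree.query_ball_point(coords[h], r=h_dist_cutoff)
                for j in near:
                    a = int(acceptors[j])
                    if atoms[a].residue_key == atoms[d].residue_key:
                        continue
                    v1 = coords[d] - coords[h]
                    v2 = coords[a] - coords[h]
                    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                    if denom < 1e-12:
                        continue
                    ang = np.degrees(np.arccos(
                        np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)))
                    if ang >= angle_cutoff:
                        out.add((int(d), a))
    else:
        logger.debug("no hydrogens: using %.2f Å heavy-atom H-bond fallback",
                     heavy_fallback_cutoff)
        for d in donors:
            near = acc_tree.query_ball_point(coords[d],
                                             r=heavy_fallback_cutoff)
            for j in near:
                a = int(acceptors[j])
                if atoms[a].residue_key != atoms[d].residue_key:
                    out.add((int(d), a))
    return out


def _residue_pair(atoms, i: int, j: int) -> tuple:
    ki, kj = atoms[i].residue_key, atoms[j].residue_key
    return (ki, kj) if ki <= kj else (kj, ki)


def detect_contacts_by_class(coords: np.ndarray, classes: AtomClassMap,
                             kind: str) -> set[tuple]:
    """Typed residue-pair contacts in one frame.

    ``kind`` is ``saltbridge``, ``pi_stacking`` or ``hydrophobic``; the
    result is a set of unordered residue-key pairs
    ((chain, resnum, icode), (chain, resnum, icode)).
    """
    coords = np.asarray(coords)
    atoms = classes.system.atoms
    out: set[tuple] = set()
    if kind == "saltbridge":
        cat = np.flatnonzero(classes.cationic)
        ani = np.flatnonzero(classes.anionic)
        if cat.size and ani.size:
            d = np.linalg.norm(coords[cat][:, None, :]
                               - coords[ani][None, :, :], axis=2)
            for ii, jj in zip(*np.nonzero(d <= 4.0)):
                i, j = int(cat[ii]), int(ani[jj])
                if atoms[i].residue_key != atoms[j].residue_key:
                    out.add(_residue_pair(atoms, i, j))
    elif kind == "pi_stacking":
        rings = classes.aromatic_rings
        for a in range(len(rings)):
            for b in range(a + 1, len(rings)):
                ra, rb = rings[a], rings[b]
                if atoms[ra[0]].residue_key == atoms[rb[0]].residue_key:
                    continue
                ca = coords[ra].mean(axis=0)
                cb = coords[rb].mean(axis=0)
                if np.linalg.norm(ca - cb) > 5.5:
                    continue
                na = _ring_normal(coords[ra])
                nb = _ring_normal(coords[rb])
                ang = np.degrees(np.arccos(
                    np.clip(abs(np.dot(na, nb)), 0.0, 1.0)))
                if ang <= 30.0 or 60.0 <= ang <= 90.0:
                    out.add(_residue_pair(atoms, int(ra[0]), int(rb[0])))
    elif kind == "hydrophobic":
        hyd = np.flatnonzero(classes.hydrophobic)
        if hyd.size:
            tree = cKDTree(coords[hyd])
            for ii, jj in tree.query_pairs(r=4.0):
                i, j = int(hyd[ii]), int(hyd[jj])
                if atoms[i].residue_key != atoms[j].residue_key:
                    out.add(_residue_pair(atoms, i, j))
    else:
        raise ConfigError(f"unknown contact class {kind!r}")
    return out


def _ring_normal(ring_coords: np.ndarray) -> np.ndarray:
    """Unit normal of a ring plane (least-squares via SVD)."""
    centered = ring_coords - ring_coords.mean(axis=0)
    _u, _s, vt = np.linalg.svd(centered)
    return vt[2]


# --------------------------------------------------------------------------
# scoring and aggregation
# --------------------------------------------------------------------------


def score_kernel(d: np.ndarray | float) -> np.ndarray | float:
    """Sigmoidal contact weight w(d) = 1/(1 + exp(5·(d − 4 Å)))."""
    return 1.0 / (1.0 + np.exp(5.0 * (np.asarray(d, dtype=float) - 4.0)))


@dataclass
class TimelineStats:
    lifetime_fraction: float
    episodes: tuple[tuple[int, int], ...]   # inclusive (start, end) frames
    mean_episode_length: float              # frames; 0.0 with no episode


@dataclass
class InteractionRecord:
    """One residue pair (or residue-ligand pair) across a trajectory."""

    residue_a: tuple[str, int, str]     # (chain, residue_number, resname)
    residue_b: tuple[str, int, str]
    interaction_class: str              # one of CLASS_PRECEDENCE
    per_frame_score: np.ndarray = field(repr=False)
    mean_score: float = 0.0
    lifetime_fraction: float = 0.0
    episodes: tuple[tuple[int, int], ...] = ()
    presence_threshold: float = 0.5

    @property
    def pair_key(self) -> tuple:
        return (self.residue_a, self.residue_b)


def aggregate_timeline(record: InteractionRecord,
                       presence_threshold: float | None = None
                       ) -> TimelineStats:
    """Lifetime fraction, contact episodes and mean episode duration.

    A frame counts as present when its score exceeds the presence
    threshold (default: the record's own).  Episodes are maximal runs of
    present frames, inclusive on both ends.
    """
    thr = record.presence_threshold if presence_threshold is None \
        else presence_threshold
    present = np.asarray(record.per_frame_score) > thr
    n = present.size
    if n == 0:
        raise DomainError("record has no frames")
    lifetime = float(present.mean())
    episodes: list[tuple[int, int]] = []
    start = None
    for i, p in enumerate(present):
        if p and start is None:
            start = i
        elif not p and start is not None:
            episodes.append((start, i - 1))
            start = None
    if start is not None:
        episodes.append((start, n - 1))
    mean_len = float(np.mean([e - s + 1 for s, e in episodes])) \
        if episodes else 0.0
    return TimelineStats(lifetime, tuple(episodes), mean_len)


def score_residue_pairs(trajectory: Trajectory, group_a: np.ndarray,
                        group_b: np.ndarray, classes: AtomClassMap,
                        threshold: float | None = None,
                        classify: bool = True) -> list[InteractionRecord]:
    """Score all inter-group residue pairs over a trajectory.

    Per frame, the pair score sums ``score_kernel`` over heavy-atom pairs
    within 6 Å between the groups.  Pairs are retained when the mean score
    over all frames exceeds ``threshold`` (default 1.0, or 0.1 when either
    group is entirely HETATM, the protein–ligand convention).  Retained
    pairs get a class label from the dominant per-frame detector hit
    (precedence hbond > saltbridge > π-stacking > hydrophobic > other) and
    lifetime statistics at presence threshold = retention threshold × 0.5.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if group_a.size == 0 or group_b.size == 0:
        raise DomainError("interaction groups must be non-empty")
    if np.intersect1d(group_a, group_b).size:
        raise DomainError("interaction groups overlap")
    if trajectory.n_frames == 0:
        raise DomainError("empty trajectory")
    atoms = trajectory.system.atoms
    heavy = classes.heavy
    ga = group_a[heavy[group_a]]
    gb = group_b[heavy[group_b]]
    if threshold is None:
        lig_like = all(atoms[i].is_hetero for i in ga) \
            or all(atoms[i].is_hetero for i in gb)
        threshold = PROTEIN_LIGAND_THRESHOLD if lig_like \
            else PROTEIN_PROTEIN_THRESHOLD

    n_frames = trajectory.n_frames
    scores: dict[tuple, np.ndarray] = {}
    pair_res: dict[tuple, tuple] = {}
    for f in range(n_frames):
        coords = trajectory.frames[f]
        tree_b = cKDTree(coords[gb])
        pairs = cKDTree(coords[ga]).query_ball_tree(
            tree_b, r=SCORE_DISTANCE_CUTOFF)
        for ia, blist in enumerate(pairs):
            if not blist:
                continue
            i = int(ga[ia])
            for jb in blist:
                j = int(gb[jb])
                d = float(np.linalg.norm(coords[i] - coords[j]))
                key = _residue_pair(atoms, i, j)
                if key not in scores:
                    scores[key] = np.zeros(n_frames)
                    pair_res[key] = key
                scores[key][f] += score_kernel(d)

    records: list[InteractionRecord] = []
    by_res = trajectory.system.atoms_by_residue()
    for key, series in scores.items():
        mean = float(series.mean())
        if mean <= threshold:
            continue
        ka, kb = key
        ra = by_res[ka][0]
        rb = by_res[kb][0]
        rec = InteractionRecord(
            residue_a=(ka[0], ka[1], atoms[ra].residue_name),
            residue_b=(kb[0], kb[1], atoms[rb].residue_name),
            interaction_class="other",
            per_frame_score=series,
            mean_score=mean,
            presence_threshold=threshold * PRESENCE_FACTOR,
        )
        stats = aggregate_timeline(rec)
        rec.lifetime_fraction = stats.lifetime_fraction
        rec.episodes = stats.episodes
        records.append(rec)

    if classify and records:
        _assign_classes(trajectory, classes, records)
    records.sort(key=lambda r: (-r.mean_score, r.residue_a, r.residue_b))
    return records


def _assign_classes(trajectory: Trajectory, classes: AtomClassMap,
                    records: list[InteractionRecord]) -> None:
    """Label each record with its dominant detected interaction type."""
    atoms = trajectory.system.atoms
    wanted = {((r.residue_a[0], r.residue_a[1]),
               (r.residue_b[0], r.residue_b[1])): r for r in records}

    def short(pair):
        (ca, na, _ia), (cb, nb, _ib) = pair
        return ((ca, na), (cb, nb))

    counts = {k: dict.fromkeys(CLASS_PRECEDENCE[:4], 0) for k in wanted}
    for f in range(trajectory.n_frames):
        coords = trajectory.frames[f]
        for d, a in detect_hbonds(coords, classes):
            key = short(_residue_pair(atoms, d, a))
            if key in counts:
                counts[key]["hbond"] += 1
        for kind in ("saltbridge", "pi_stacking", "hydrophobic"):
            for pair in detect_contacts_by_class(coords, classes, kind):
                key = short(pair)
                if key in counts:
                    counts[key][kind] += 1
    for key, rec in wanted.items():
        cnt = counts[key]
        best = max(cnt.values())
        if best == 0:
            rec.interaction_class = "other"
        else:
            for cls in CLASS_PRECEDENCE[:4]:
                if cnt[cls] == best:
                    rec.interaction_class = cls
                    break


# --------------------------------------------------------------------------
# consensus across replicas
# --------------------------------------------------------------------------


@dataclass
class PairConsensus:
    runs_present: int
    mean_lifetime: float          # mean lifetime_fraction over present runs
    interaction_class: str        # highest-precedence class seen
    persistent_runs: int          # runs with lifetime >= persistent_fraction


@dataclass
class ConsensusNetwork:
    """Cross-replica summary of an interaction network."""

    n_runs: int
    pairs: dict[tuple, PairConsensus]
    persistent_fraction: float

    @property
    def in_all_runs(self) -> set[tuple]:
        return {k for k, v in self.pairs.items()
                if v.runs_present == self.n_runs}

    def persistent_per_run_counts(self,
                                  records_per_run: list[list[
                                      InteractionRecord]]) -> list[int]:
        return [sum(r.lifetime_fraction >= self.persistent_fraction
                    for r in run) for run in records_per_run]


def cross_run_consensus(records_per_run: list[list[InteractionRecord]],
                        persistent_fraction: float = 0.9
                        ) -> ConsensusNetwork:
    """Combine per-run interaction records into a consensus network.

    The "formed in all runs" set contains pairs present (retained) in every
    run; "persistent" means lifetime_fraction ≥ ``persistent_fraction``
    within one run.  Invariant to run ordering.
    """
    if not records_per_run:
        raise DomainError("at least one run required")
    n_runs = len(records_per_run)
    acc: dict[tuple, list] = {}
    for run in records_per_run:
        for rec in run:
            entry = acc.setdefault(rec.pair_key, [0, [], []])
            entry[0] += 1
            entry[1].append(rec.lifetime_fraction)
            entry[2].append(rec.interaction_class)
    pairs = {}
    for key, (count, lifes, cls) in acc.items():
        best = min(cls, key=CLASS_PRECEDENCE.index)
        pairs[key] = PairConsensus(
            runs_present=count,
            mean_lifetime=float(np.mean(lifes)),
            interaction_class=best,
            persistent_runs=sum(lf >= persistent_fraction for lf in lifes),
        )
    return ConsensusNetwork(n_runs, pairs, persistent_fraction)
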