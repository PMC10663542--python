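"""Seeded toy-system generators with exact ground truth.

Real microsecond-scale MD of a solvated protein complex cannot be rerun on
a desk machine, so every statistic the pipeline computes is exercised
against generators whose hidden state is known by construction:

* :func:`simulate_hinge_trajectory` — a three-domain bead molecule whose
  hinge angle follows a two-state (straight/boomerang) discrete-time Markov
  chain with Gaussian angle noise, realized as coordinates whose domain
  centers of mass subtend exactly the drawn angle.
* :func:`simulate_contact_telegraph` — a binary on/off Markov (telegraph)
  process with state-dependent Gaussian distance emissions, the toy model
  of a short-lived interface contact.
* :func:`simulate_ligand_capture` — a ligand random walk from 50 Å out,
  funnelled into an absorbing pocket at the center of a cage of receptor
  pseudo-residues.

All generators are pure functions of their parameter dataclasses (seed
included): the same params give bit-identical output.  Discrete-time
per-frame transition probabilities are used throughout; with frame spacing
Δt they map onto rates as p ≈ k·Δt.

The module also builds deterministic *synthetic stand-in* reference
structures (:func:`synthetic_hinge_reference`,
:func:`synthetic_interface_reference`): crystal-structure-scale fixtures
whose hinge angles / buried interface area are constructed at the published
crystal values, for use where the real PDB entries are not shipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .errors import ConfigError, DomainError
from .geometry import DomainDefinition
from .pdbio import write_structure, write_trajectory
from .systems import AtomRecord, MolecularSystem, Trajectory

STRAIGHT, BOOMERANG = 0, 1

# ---------------------------------------------------------------------------
# hinge-angle Markov model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HingeModelParams:
    """Two-state hinge-switching model.

    Defaults emulate the published study conditions: 2000 frames per 200 ns
    run, straight/boomerang means bracketing the 140° threshold at the two
    crystal angles, a boomerang occupancy near 12.5%
    (p_sb/(p_sb+p_bs) = 0.125), and ~4° of angle noise.
    """

    n_frames: int = 2000
    p_sb: float = 0.0125     # straight -> boomerang, per frame
    p_bs: float = 0.0875     # boomerang -> straight, per frame
    mu_straight: float = 146.7
    mu_boomerang: float = 129.4
    sigma: float = 4.0
    seed: int = 0
    frame_interval_ns: float = 0.1

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        for name in ("p_sb", "p_bs"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.sigma < 0:
            raise ConfigError("sigma must be non-negative")

    @property
    def stationary_boomerang(self) -> float:
        """Stationary probability of the boomerang state."""
        tot = self.p_sb + self.p_bs
        return 0.5 if tot == 0 else self.p_sb / tot


@dataclass(frozen=True)
class HingeSimulation:
    """A simulated hinge trajectory with its hidden ground truth."""

    trajectory: Trajectory
    states: np.ndarray          # per-frame hidden state (0 straight, 1 boom.)
    angles: np.ndarray          # per-frame drawn angle (deg)
    n_transitions: int          # hidden-state changes, frame to frame
    params: HingeModelParams


_DOMAIN_RESNAMES = ("FHB", "HNG", "IGL")   # 4HB / hinge / Ig-like beads
_ARM_LENGTH = 25.0                          # Å, COM-to-COM arm


def toy_hinge_system() -> MolecularSystem:
    """Topology of the 9-bead hinge molecule: three 3-bead domains
    (residues 1, 2, 3 on chain A), all carbons."""
    atoms = []
    aid = 1
    for res, resname in enumerate(_DOMAIN_RESNAMES, start=1):
        for k in range(3):
            atoms.append(AtomRecord(
                atom_id=aid, atom_name=f"C{k + 1}", element="C",
                residue_name=resname, residue_number=res, chain_id="A"))
            aid += 1
    coords = _hinge_frame_coords(np.array([150.0]))[0]
    return MolecularSystem(atoms, coords)


def toy_hinge_domains() -> tuple[DomainDefinition, DomainDefinition,
                                 DomainDefinition]:
    """Domain definitions (4HB, hinge, Ig-like) for the 9-bead molecule."""
    return (DomainDefinition("4HB", {"A": ((1, 1),)}),
            DomainDefinition("hinge", {"A": ((2, 2),)}),
            DomainDefinition("Ig-like", {"A": ((3, 3),)}))


# Equilateral-triangle bead offsets around each domain COM, chosen in the
# plane perpendicular to the respective arm so the bead COM is exact and the
# beads never straddle domains.
_TRI = 1.5 * np.array([[0.0, 1.0, 0.0], [np.sqrt(3) / 2, -0.5, 0.0],
                       [-np.sqrt(3) / 2, -0.5, 0.0]])
_TRI_Z = 1.5 * np.array([[0.0, 0.0, 1.0], [0.0, np.sqrt(3) / 2, -0.5],
                         [0.0, -np.sqrt(3) / 2, -0.5]])


def _hinge_frame_coords(angles_deg: np.ndarray) -> np.ndarray:
    """Coordinates (n_frames, 9, 3) whose domain COMs subtend the given
    angles: hinge COM at the origin, 4HB COM on +x, Ig-like COM rotated in
    the xy-plane."""
    theta = np.radians(angles_deg)
    n = len(theta)
    coords = np.empty((n, 9, 3))
    com_4hb = np.array([_ARM_LENGTH, 0.0, 0.0])
    com_ig = _ARM_LENGTH * np.column_stack(
        [np.cos(theta), np.sin(theta), np.zeros(n)])
    coords[:, 0:3, :] = com_4hb + _TRI_Z                    # 4HB beads
    coords[:, 3:6, :] = _TRI                                # hinge beads
    coords[:, 6:9, :] = com_ig[:, None, :] + _TRI_Z         # Ig-like beads
    return coords


def hinge_trajectory_from_angles(angles_deg: np.ndarray,
                                 frame_interval_ns: float = 0.1
                                 ) -> Trajectory:
    """Realize an arbitrary hinge-angle series as a 9-bead trajectory
    (each frame's domain COMs subtend exactly the given angle)."""
    angles_deg = np.asarray(angles_deg, dtype=float)
    frames = _hinge_frame_coords(angles_deg)
    times = np.arange(len(angles_deg)) * frame_interval_ns
    return Trajectory(toy_hinge_system(), frames, times)


def _markov_chain(rng: np.random.Generator, n: int, p01: float, p10: float,
                  start: int) -> np.ndarray:
    """Binary Markov chain; p01 = P(0->1), p10 = P(1->0)."""
    states = np.empty(n, dtype=np.int8)
    states[0] = start
    u = rng.random(n - 1) if n > 1 else np.empty(0)
    s = start
    for i in range(1, n):
        s = (1 - s) if u[i - 1] < (p01 if s == 0 else p10) else s
        states[i] = s
    return states


def simulate_hinge_trajectory(params: HingeModelParams) -> HingeSimulation:
    """Simulate the two-state hinge model and realize it as coordinates.

    The hidden chain starts from a draw of its stationary distribution.
    With ``sigma = 0`` the hinge angle recomputed from the emitted
    coordinates equals the state means to floating-point accuracy.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    start = int(rng.random() < params.stationary_boomerang)
    states = _markov_chain(rng, params.n_frames, params.p_sb, params.p_bs,
                           start)
    means = np.where(states == BOOMERANG, params.mu_boomerang,
                     params.mu_straight)
    angles = means + params.sigma * rng.standard_normal(params.n_frames)
    angles = np.clip(angles, 1e-6, 180.0 - 1e-6)
    frames = _hinge_frame_coords(angles)
    system = toy_hinge_system()
    times = np.arange(params.n_frames) * params.frame_interval_ns
    traj = Trajectory(system, frames, times)
    n_trans = int(np.count_nonzero(states[1:] != states[:-1]))
    return HingeSimulation(traj, states, angles, n_trans, params)


# ---------------------------------------------------------------------------
# contact telegraph process
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TelegraphParams:
    """On/off contact process with distance emissions.

    Defaults emulate a short-lived interface bond: stationary on-fraction
    p_on/(p_on+p_off) = 0.2 (the published 400/2000-frame lifetime), a bound
    distance around 3 Å and an unbound distance around 8 Å.
    """

    n_frames: int = 2000
    p_on: float = 0.02       # off -> on, per frame
    p_off: float = 0.08      # on -> off, per frame
    d_on_mean: float = 3.0
    d_on_sd: float = 0.3
    d_off_mean: float = 8.0
    d_off_sd: float = 1.0
    seed: int = 0
    start_state: int | None = None   # 1 on / 0 off; None -> stationary draw

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        for name in ("p_on", "p_off"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.d_on_mean >= self.d_off_mean:
            raise ConfigError("d_on_mean must be below d_off_mean")
        if min(self.d_on_sd, self.d_off_sd) < 0:
            raise ConfigError("distance SDs must be non-negative")

    @property
    def stationary_on(self) -> float:
        tot = self.p_on + self.p_off
        return 0.0 if tot == 0 else self.p_on / tot


@dataclass(frozen=True)
class TelegraphSimulation:
    distances: np.ndarray    # per-frame emitted distance (Å, positive)
    states: np.ndarray       # per-frame ground-truth on(1)/off(0)
    params: TelegraphParams


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Normal(mean, sd) truncated to positive values."""
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                         random_state=rng)


def simulate_contact_telegraph(params: TelegraphParams) -> TelegraphSimulation:
    """Simulate the on/off contact chain and its distance emissions."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    if params.start_state is None:
        start = int(rng.random() < params.stationary_on)
    else:
        start = int(params.start_state)
    # chain is stored with on = 1: p(off->on) plays the 0->1 role
    states = _markov_chain(rng, params.n_frames, params.p_on, params.p_off,
                           start)
    distances = np.where(
        states == 1,
        _truncated_normal(rng, params.d_on_mean, params.d_on_sd,
                          params.n_frames),
        _truncated_normal(rng, params.d_off_mean, params.d_off_sd,
                          params.n_frames))
    return TelegraphSimulation(distances, states, params)


# ---------------------------------------------------------------------------
# ligand capture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaptureParams:
    """Ligand random walk with an absorbing pocket.

    The ligand starts ``start_distance`` (default 50 Å, the published
    placement) from the pocket center, drifts weakly toward it
    (``drift`` Å/frame; the far-field funnel that stands in for the fraction
    of runs where diffusion finds the pocket), walks with Gaussian steps of
    ``step_sd``, is strongly steered once within ``2 * capture_radius``,
    and is absorbed (small-jitter bound state) within ``capture_radius``.
    """

    n_frames: int = 400
    start_distance: float = 50.0
    step_sd: float = 1.0
    capture_radius: float = 3.0
    pocket_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    drift: float = 0.3
    contact_cutoff: float = 4.0
    seed: int = 0
    frame_interval_ns: float = 0.1

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.start_distance <= 0:
            raise ConfigError("start_distance must be positive")
        if self.capture_radius <= 0:
            raise ConfigError("capture_radius must be positive")
        if self.step_sd < 0 or self.drift < 0:
            raise ConfigError("step_sd and drift must be non-negative")


@dataclass(frozen=True)
class CaptureSimulation:
    """Capture trajectory (receptor cage + 1-atom ligand) and ground truth.

    ``first_contact_frame`` is the first frame with any ligand-receptor
    heavy-atom distance at or below ``params.contact_cutoff``;
    ``capture_frame`` the first absorbed frame; both ``None`` when the event
    never happened.
    """

    trajectory: Trajectory
    ligand_indices: np.ndarray
    receptor_indices: np.ndarray
    pocket_residues: tuple[tuple[str, int, str], ...]
    first_contact_frame: int | None
    capture_frame: int | None
    bound_mask: np.ndarray
    params: CaptureParams


_CAGE_RADIUS = 3.5   # Å, receptor pseudo-residue shell around the pocket
_N_CAGE = 12


def _cage_coordinates(center: np.ndarray) -> np.ndarray:
    """Icosahedron-vertex cage of receptor atoms around the pocket center."""
    phi = (1 + np.sqrt(5)) / 2
    verts = np.array([[0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
                      [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
                      [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1]],
                     dtype=float)
    verts /= np.linalg.norm(verts[0])
    return center + _CAGE_RADIUS * verts


def capture_system(params: CaptureParams) -> MolecularSystem:
    """Receptor cage (chain R, 12 single-atom residues) plus a one-atom
    hetero ligand (chain L, residue LIG 1)."""
    center = np.asarray(params.pocket_center, dtype=float)
    cage = _cage_coordinates(center)
    atoms = [AtomRecord(i + 1, "CA", "C", "PKT", i + 1, "R")
             for i in range(_N_CAGE)]
    atoms.append(AtomRecord(_N_CAGE + 1, "C1", "C", "LIG", 1, "L",
                            is_hetero=True))
    start = center + np.array([params.start_distance, 0.0, 0.0])
    coords = np.vstack([cage, start[None, :]])
    return MolecularSystem(atoms, coords)


def simulate_ligand_capture(params: CaptureParams) -> CaptureSimulation:
    """Run the capture walk and emit trajectory plus ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    system = capture_system(params)
    center = np.asarray(params.pocket_center, dtype=float)
    cage = system.reference_coordinates[:_N_CAGE]
    pos = system.reference_coordinates[_N_CAGE].copy()
    n = params.n_frames
    lig = np.empty((n, 3))
    bound = np.zeros(n, dtype=bool)
    absorbed = np.linalg.norm(pos - center) <= params.capture_radius
    for t in range(n):
        # frame t records the position *before* this frame's displacement,
        # so frame 0 shows the initial 50 Å placement
        lig[t] = pos
        bound[t] = absorbed
        if absorbed:
            pos = center + 0.05 * rng.standard_normal(3)
            continue
        to_center = center - pos
        dist = np.linalg.norm(to_center)
        step = params.step_sd * rng.standard_normal(3)
        if params.step_sd > 0:
            if dist <= 2.0 * params.capture_radius:
                # strong steering inside the bias zone
                step += to_center / max(dist, 1e-9) \
                    * min(dist, 3.0 * params.step_sd)
            elif params.drift > 0:
                step += params.drift * to_center / max(dist, 1e-9)
        pos = pos + step
        if np.linalg.norm(pos - center) <= params.capture_radius:
            absorbed = True
            pos = center + 0.05 * rng.standard_normal(3)
    frames = np.empty((n, _N_CAGE + 1, 3))
    frames[:, :_N_CAGE, :] = cage
    frames[:, _N_CAGE, :] = lig
    times = np.arange(n) * params.frame_interval_ns
    traj = Trajectory(system, frames, times)
    mind = np.linalg.norm(lig[:, None, :] - cage[None, :, :],
                          axis=2).min(axis=1)
    contact_frames = np.flatnonzero(mind <= params.contact_cutoff)
    first_contact = int(contact_frames[0]) if contact_frames.size else None
    cap_frames = np.flatnonzero(bound)
    capture = int(cap_frames[0]) if cap_frames.size else None
    pocket_keys = tuple(("R", i + 1, "") for i in range(_N_CAGE))
    return CaptureSimulation(
        trajectory=traj,
        ligand_indices=np.array([_N_CAGE]),
        receptor_indices=np.arange(_N_CAGE),
        pocket_residues=pocket_keys,
        first_contact_frame=first_contact,
        capture_frame=capture,
        bound_mask=bound,
        params=params,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_toy_system(trajectory: Trajectory, directory: str | Path
                      ) -> tuple[Path, Path]:
    """Write a trajectory bundle into ``directory``: ``topology.pdb`` (the
    system's reference coordinates) and ``trajectory.pdb`` (multi-model).
    Returns the two paths; both re-read losslessly at PDB precision
    (3 decimals)."""
    if trajectory.n_frames < 1:
        raise DomainError("cannot export an empty trajectory")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    top = directory / "topology.pdb"
    trj = directory / "trajectory.pdb"
    write_structure(trajectory.system, top)
    write_trajectory(trajectory, trj)
    return top, trj


# ---------------------------------------------------------------------------
# synthetic stand-in reference structures
# ---------------------------------------------------------------------------

#: Default three-domain residue boundaries for an IZUMO1-like ectodomain
#: (residues 22-254): four-helix bundle, hinge, Ig-like domain.  The real
#: domain boundaries are not published; these are the package's calibratable
#: defaults and are exactly the ranges the synthetic reference embodies.
IZUMO1_DOMAIN_RANGES: dict[str, tuple[int, int]] = {
    "4HB": (22, 133), "hinge": (134, 166), "Ig-like": (167, 254),
}

#: Published crystal hinge angles the stand-ins are built at.
CRYSTAL_HINGE_ANGLES = {"straight": 146.7, "boomerang": 129.4}


def izumo1_domain_definitions(chain: str = "A") -> tuple[DomainDefinition,
                                                         DomainDefinition,
                                                         DomainDefinition]:
    """(4HB, hinge, Ig-like) domain definitions on one chain."""
    return tuple(DomainDefinition(label, {chain: ((lo, hi),)})
                 for label, (lo, hi) in IZUMO1_DOMAIN_RANGES.items())


def synthetic_hinge_reference(conformation: str = "straight"
                              ) -> MolecularSystem:
    """Synthetic stand-in for an IZUMO1 ectodomain crystal structure.

    A Cα-trace-scale bead model (one carbon per residue, 22-254, chain A)
    whose three domain clouds are deterministic point sets recentred so the
    domain centers of mass subtend exactly the published crystal hinge
    angle: 146.7° ("straight") or 129.4° ("boomerang").  It is *not* the
    crystal structure — it is a constructed fixture for exercising the
    structure -> selection -> COM -> hinge-angle path at realistic scale.
    """
    if conformation not in CRYSTAL_HINGE_ANGLES:
        raise ConfigError(f"unknown conformation {conformation!r}")
    angle = CRYSTAL_HINGE_ANGLES[conformation]
    theta = np.radians(angle)
    com_targets = {
        "4HB": np.array([_ARM_LENGTH, 0.0, 0.0]),
        "hinge": np.zeros(3),
        "Ig-like": _ARM_LENGTH * np.array([np.cos(theta), np.sin(theta), 0.0]),
    }
    rng = np.random.default_rng(20230)   # fixed: the stand-in is one object
    atoms, coords = [], []
    aid = 1
    for label, (lo, hi) in IZUMO1_DOMAIN_RANGES.items():
        n_res = hi - lo + 1
        cloud = rng.normal(scale=6.0, size=(n_res, 3))
        cloud -= cloud.mean(axis=0)          # exact centroid at the target
        cloud += com_targets[label]
        for k in range(n_res):
            atoms.append(AtomRecord(aid, "CA", "C", "GLY", lo + k, "A"))
            coords.append(cloud[k])
            aid += 1
    return MolecularSystem(atoms, np.array(coords))


#: Geometry of the two-slab interface stand-in (see
#: :func:`synthetic_interface_reference`): grid size, spacing (Å) and
#: inter-slab gap (Å), fixed so the per-side buried area falls in the
#: published 842-910 Å² crystal-interface band.
_SLAB_N = 11
_SLAB_SPACING = 2.45
_SLAB_GAP = 4.6


def synthetic_interface_reference() -> MolecularSystem:
    """Synthetic stand-in for a receptor–ligand-protein crystal complex.

    Two parallel square slabs of carbon pseudo-atoms (chains A and B, one
    single-atom residue per grid point) facing each other across a
    solvent-excluding gap.  The slab size and gap are fixed so the buried
    interface area, (SASA_A + SASA_B - SASA_AB)/2 at probe 1.4 Å, lies in
    the 842-910 Å² band reported for the crystal complexes.  A constructed
    fixture, not the crystal structure.
    """
    n, a, gap = _SLAB_N, _SLAB_SPACING, _SLAB_GAP
    grid = (np.arange(n) - (n - 1) / 2) * a
    xx, yy = np.meshgrid(grid, grid, indexing="ij")
    atoms, coords = [], []
    aid = 1
    for chain, z in (("A", 0.0), ("B", gap)):
        for k, (x, y) in enumerate(zip(xx.ravel(), yy.ravel()), start=1):
            atoms.append(AtomRecord(aid, "CA", "C", "SLB", k, chain))
            coords.append([x, y, z])
            aid += 1
    return MolecularSystem(atoms, np.array(coords))
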