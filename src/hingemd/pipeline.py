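"""Config-driven orchestration of the analysis stages.

A single YAML/JSON config names the inputs (a structure plus a trajectory,
or a synthetic-simulation block), the chain/domain/pocket/site definitions
and every threshold; :func:`run_analysis` executes the requested stages in
dependency order and writes per-stage TSV/JSON reports plus a summary JSON
and a manifest (config hash + package version).  Identical config and
inputs give byte-identical outputs.

Stages
------
``simulate``  generate a synthetic bundle (hinge or capture) into the
              output directory and use it as the run input
``hinge``     hinge-angle timeline, state labels, occupancies, shifts,
              dwell statistics, 1°-bin histogram
``contacts``  residue-pair interaction records and lifetime statistics
``area``      per-frame buried interface area with mean/SD/min/max
``ligand``    ligand first contact, state series, insertion depth,
              bound intervals
``ion``       ion-site residence (bound flags, coordination counts)
``cluster``   unbiased RMSD clustering of frames
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .binding import IonSite, classify_ligand_state, ion_site_tracking
from .conformation import (angle_histogram, classify_conformations,
                           cluster_states, occupancy_and_dwell)
from .contacts import (classify_atoms, cross_run_consensus,
                       score_residue_pairs)
from .errors import ConfigError, HingemdError
from .geometry import DomainDefinition
from .pdbio import read_structure, read_trajectory, write_table
from .sasa import buried_interface_area, vdw_radii
from .selection import select_atoms
from .synthetic import (CaptureParams, HingeModelParams, export_toy_system,
                        simulate_hinge_trajectory, simulate_ligand_capture,
                        toy_hinge_domains)
from .systems import Trajectory

logger = logging.getLogger(__name__)

ALL_TASKS = ("simulate", "hinge", "contacts", "area", "ligand", "ion",
             "cluster")

_DEFAULT_THRESHOLDS = {
    "hinge_threshold_deg": 140.0,
    "hbond_h_cutoff": 2.5,
    "hbond_angle_cutoff": 120.0,
    "hbond_heavy_cutoff": 3.5,
    "protein_score_threshold": 1.0,
    "ligand_score_threshold": 0.1,
    "contact_cutoff": 4.0,
    "ion_cutoff": 3.0,
    "persistent_fraction": 0.9,
    "probe_radius": 1.4,
    "sasa_points": 960,
}


@dataclass
class AnalysisConfig:
    """Validated analysis configuration.

    Built from a YAML/JSON mapping via :meth:`from_file` /
    :meth:`from_dict`; unknown stage blocks are rejected, thresholds must
    be positive, and referenced chains/residues are checked against the
    topology before any stage runs.
    """

    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "AnalysisConfig":
        cfg = cls(raw=dict(data))
        cfg.validate_static()
        return cfg

    # -- accessors ---------------------------------------------------------
    def get(self, key: str, default: Any = None) -> Any:
        return self.raw.get(key, default)

    def threshold(self, name: str) -> float:
        val = self.raw.get("thresholds", {}).get(name,
                                                 _DEFAULT_THRESHOLDS[name])
        return val

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def output_dir(self) -> Path:
        return Path(self.raw.get("output_dir", "hingemd_out"))

    def config_hash(self) -> str:
        # output_dir does not affect what is computed, only where it lands
        payload = {k: v for k, v in self.raw.items() if k != "output_dir"}
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    # -- validation --------------------------------------------------------
    def validate_static(self) -> None:
        known = set(ALL_TASKS) | {
            "structure", "trajectory", "trajectory_dialect",
            "frame_interval_ns", "seed", "output_dir", "thresholds",
        }
        unknown = set(self.raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        thr = self.raw.get("thresholds", {})
        for key, val in thr.items():
            if key not in _DEFAULT_THRESHOLDS:
                raise ConfigError(f"unknown threshold {key!r}")
            if not isinstance(val, (int, float)) or val <= 0:
                raise ConfigError(f"threshold {key!r} must be positive")

    def domain_definitions(self) -> tuple[DomainDefinition, ...]:
        block = self.raw.get("hinge", {}) or {}
        doms = block.get("domains")
        if doms is None:
            return toy_hinge_domains()
        out = []
        for label, spec in doms.items():
            chain = spec.get("chain", "A")
            ranges = tuple(tuple(r) for r in spec["ranges"])
            out.append(DomainDefinition(label, {chain: ranges}))
        if len(out) != 3:
            raise ConfigError("hinge analysis needs exactly three domains")
        return tuple(out)

    def validate_against(self, trajectory: Trajectory,
                         tasks: Sequence[str]) -> None:
        """Check that referenced chains/residues exist before computing."""
        system = trajectory.system
        chains = system.chains
        if "hinge" in tasks or "cluster" in tasks:
            for dom in self.domain_definitions():
                for chain in dom.residue_ranges:
                    if chain not in chains:
                        raise ConfigError(
                            f"domain {dom.label!r} references chain "
                            f"{chain!r} absent from the topology")
                if dom.atom_indices(system).size == 0:
                    raise ConfigError(
                        f"domain {dom.label!r} selects no atoms")
        for stage, keys in (("contacts", ("group_a", "group_b")),
                            ("area", ("group_a", "group_b"))):
            if stage in tasks:
                block = self.raw.get(stage, {}) or {}
                for key in keys:
                    expr = block.get(key)
                    if expr is None:
                        raise ConfigError(
                            f"{stage} stage needs selection {key!r}")
                    if select_atoms(system, expr).size == 0:
                        raise ConfigError(
                            f"{stage}.{key} selection {expr!r} is empty")


def _load_input(config: AnalysisConfig, outdir: Path,
                tasks: Sequence[str]) -> tuple[Trajectory, dict]:
    """Load the structure+trajectory, or generate the simulated bundle."""
    sim_info: dict = {}
    if "simulate" in tasks or (config.get("simulate")
                               and not config.get("trajectory")):
        block = config.get("simulate") or {}
        kind = block.get("kind", "hinge")
        params_kw = dict(block.get("params", {}))
        params_kw.setdefault("seed", config.seed)
        if kind == "hinge":
            sim = simulate_hinge_trajectory(HingeModelParams(**params_kw))
            traj = sim.trajectory
            sim_info = {
                "kind": "hinge",
                "n_transitions": sim.n_transitions,
                "stationary_boomerang": sim.params.stationary_boomerang,
            }
        elif kind == "capture":
            sim = simulate_ligand_capture(CaptureParams(**params_kw))
            traj = sim.trajectory
            sim_info = {
                "kind": "capture",
                "first_contact_frame": sim.first_contact_frame,
                "capture_frame": sim.capture_frame,
            }
        else:
            raise ConfigError(f"unknown simulation kind {kind!r}")
        export_toy_system(traj, outdir / "synthetic_input")
        return traj, sim_info
    structure = config.get("structure")
    trajectory = config.get("trajectory")
    if structure is None:
        raise ConfigError("config needs 'structure' (or a simulate block)")
    system = read_structure(structure)
    if trajectory is None:
        traj = Trajectory(system, system.reference_coordinates[None],
                          np.zeros(1))
    else:
        traj = read_trajectory(
            trajectory, system,
            dialect=config.get("trajectory_dialect", "multi-model-pdb"),
            frame_interval_ns=config.get("frame_interval_ns"))
    return traj, sim_info


def run_analysis(config: AnalysisConfig,
                 tasks: Sequence[str] = ("all",)) -> dict:
    """Execute the requested stages and write the report bundle.

    Returns the summary dictionary (also written as ``summary.json``).
    Stage failures are logged and recorded under ``errors``; independent
    stages still run.  Raises :class:`ConfigError` before any computation
    when the config does not validate.
    """
    if "all" in tasks:
        tasks = [t for t in ALL_TASKS
                 if t == "simulate" and config.get("simulate")
                 or t != "simulate" and config.get(t) is not None]
        if not tasks:
            tasks = ["hinge"]
    unknown = set(tasks) - set(ALL_TASKS)
    if unknown:
        raise ConfigError(f"unknown tasks: {sorted(unknown)}")
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    trajectory, sim_info = _load_input(config, outdir, tasks)
    config.validate_against(trajectory, tasks)

    summary: dict[str, Any] = {"simulation": sim_info} if sim_info else {}
    errors: dict[str, str] = {}
    stages = {
        "hinge": _stage_hinge, "contacts": _stage_contacts,
        "area": _stage_area, "ligand": _stage_ligand, "ion": _stage_ion,
        "cluster": _stage_cluster,
    }
    for task in [t for t in tasks if t != "simulate"]:
        logger.info("stage %s: start", task)
        try:
            summary[task] = stages[task](config, trajectory, outdir)
        except HingemdError as exc:
            logger.error("stage %s failed: %s", task, exc)
            errors[task] = str(exc)
        logger.info("stage %s: done", task)
    if errors:
        summary["errors"] = errors
    manifest = {
        "package": "hingemd",
        "version": __version__,
        "config_hash": config.config_hash(),
        "tasks": list(tasks),
    }
    _write_json(outdir / "manifest.json", manifest)
    _write_json(outdir / "summary.json", summary)
    return summary


def _round(x: float, nd: int = 6) -> float:
    return float(np.format_float_positional(float(x), precision=nd,
                                            unique=False, fractional=False))


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               default=_json_default) + "\n")


def _json_default(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# -- stages ----------------------------------------------------------------


def _stage_hinge(config: AnalysisConfig, trajectory: Trajectory,
                 outdir: Path) -> dict:
    domains = config.domain_definitions()
    threshold = config.threshold("hinge_threshold_deg")
    timeline = classify_conformations(trajectory, domains, threshold)
    stats = occupancy_and_dwell(timeline)
    rows = [{"frame": i, "time_ns": _round(timeline.frame_times[i]),
             "angle_deg": _round(timeline.angles[i]),
             "label": ("straight", "boomerang")[int(timeline.labels[i])]}
            for i in range(timeline.n_frames)]
    write_table(rows, outdir / "hinge_timeline.tsv")
    counts, edges = angle_histogram(timeline, 1.0)
    write_table([{"bin_left_deg": _round(edges[i]), "count": int(counts[i])}
                 for i in range(len(counts))],
                outdir / "hinge_histogram.tsv")
    return {
        "threshold_deg": threshold,
        "occupancy": {k: _round(v) for k, v in stats["occupancy"].items()},
        "n_shifts": stats["n_shifts"],
        "mean_dwell_frames": {k: _round(v)
                              for k, v in stats["mean_dwell"].items()},
        "n_frames": timeline.n_frames,
    }


def _stage_contacts(config: AnalysisConfig, trajectory: Trajectory,
                    outdir: Path) -> dict:
    block = config.get("contacts", {}) or {}
    system = trajectory.system
    classes = classify_atoms(system)
    ga = select_atoms(system, block["group_a"])
    gb = select_atoms(system, block["group_b"])
    threshold = block.get("score_threshold")
    records = score_residue_pairs(trajectory, ga, gb, classes,
                                  threshold=threshold)
    rows = [{
        "residue_a": f"{r.residue_a[0]}:{r.residue_a[2]}{r.residue_a[1]}",
        "residue_b": f"{r.residue_b[0]}:{r.residue_b[2]}{r.residue_b[1]}",
        "class": r.interaction_class,
        "mean_score": _round(r.mean_score),
        "lifetime_fraction": _round(r.lifetime_fraction),
        "n_episodes": len(r.episodes),
    } for r in records]
    write_table(rows, outdir / "contacts.tsv")
    consensus = cross_run_consensus(
        [records], config.threshold("persistent_fraction"))
    return {
        "n_pairs": len(records),
        "n_persistent": consensus.persistent_per_run_counts([records])[0],
        "classes": {c: sum(r.interaction_class == c for r in records)
                    for c in sorted({r.interaction_class for r in records})},
    }


def _stage_area(config: AnalysisConfig, trajectory: Trajectory,
                outdir: Path) -> dict:
    block = config.get("area", {}) or {}
    system = trajectory.system
    ga = select_atoms(system, block["group_a"])
    gb = select_atoms(system, block["group_b"])
    radii = vdw_radii(system)
    probe = config.threshold("probe_radius")
    n_points = int(config.threshold("sasa_points"))
    areas = np.array([
        buried_interface_area(frame, ga, gb, radii, probe, n_points)
        for frame in trajectory.frames])
    write_table([{"frame": i, "buried_area_A2": _round(a)}
                 for i, a in enumerate(areas)],
                outdir / "interface_area.tsv")
    return {"mean_A2": _round(areas.mean()),
            "sd_A2": _round(areas.std(ddof=1) if len(areas) > 1 else 0.0),
            "min_A2": _round(areas.min()), "max_A2": _round(areas.max())}


def _stage_ligand(config: AnalysisConfig, trajectory: Trajectory,
                  outdir: Path) -> dict:
    block = config.get("ligand", {}) or {}
    system = trajectory.system
    lig = select_atoms(system, block.get("ligand", "hetero"))
    rec_expr = block.get("receptor")
    rec = select_atoms(system, rec_expr) if rec_expr else None
    pocket = [tuple(p) for p in block.get("pocket_residues", [])]
    if not pocket:
        raise ConfigError("ligand stage needs pocket_residues")
    event = classify_ligand_state(
        trajectory, lig, pocket, receptor=rec,
        contact_cutoff=config.threshold("contact_cutoff"),
        buried_threshold=block.get("buried_threshold", 0.4))
    from .binding import STATE_LABELS
    rows = [{"frame": i, "state": STATE_LABELS[int(event.state_series[i])],
             "insertion_depth": _round(event.insertion_depth[i])}
            for i in range(trajectory.n_frames)]
    write_table(rows, outdir / "ligand_states.tsv")
    report = {
        "ligand": list(event.ligand_id),
        "first_contact_frame": event.first_contact_frame,
        "first_contact_residue": (list(event.first_contact_residue)
                                  if event.first_contact_residue else None),
        "bound_intervals": [list(iv) for iv in event.bound_intervals],
        "max_insertion_depth": _round(event.insertion_depth.max()),
    }
    _write_json(outdir / "ligand_event.json", report)
    return report


def _stage_ion(config: AnalysisConfig, trajectory: Trajectory,
               outdir: Path) -> dict:
    block = config.get("ion", {}) or {}
    system = trajectory.system
    ion = select_atoms(system, block["ion"])
    site_spec = block.get("site", {})
    site = IonSite(
        site_id=site_spec.get("site_id", "site1"),
        coordinating_residues=tuple(tuple(r)
                                    for r in site_spec["residues"]),
        bound_cutoff=site_spec.get("cutoff",
                                   config.threshold("ion_cutoff")))
    tracking = ion_site_tracking(trajectory, ion, site)
    write_table([{"frame": i, "bound": int(tracking.bound[i]),
                  "coordination": int(tracking.coordination_count[i])}
                 for i in range(trajectory.n_frames)],
                outdir / "ion_site.tsv")
    return {"site_id": tracking.site_id,
            "ever_bound": tracking.ever_bound,
            "bound_fraction": _round(tracking.bound.mean()),
            "unbinding_frame": tracking.unbinding_frame}


def _stage_cluster(config: AnalysisConfig, trajectory: Trajectory,
                   outdir: Path) -> dict:
    block = config.get("cluster", {}) or {}
    selection = select_atoms(trajectory.system,
                             block.get("selection", "name CA"))
    k = int(block.get("k", 3))
    domains = config.domain_definitions() if config.get("hinge") else None
    labels, medoids = cluster_states(trajectory, selection, k,
                                     domains=domains)
    write_table([{"frame": i, "cluster": int(labels[i])}
                 for i in range(trajectory.n_frames)],
                outdir / "clusters.tsv")
    sizes = [int(np.sum(labels == c)) for c in range(k)]
    return {"k": k, "sizes": sizes, "medoid_frames": medoids.tolist()}
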