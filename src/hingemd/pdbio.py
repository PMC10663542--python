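"""Reading and writing structures, trajectories and report tables.

The canonical trajectory dialect is multi-model PDB (MODEL/ENDMDL blocks),
which keeps the whole pipeline runnable from plain-text inputs; DCD and XTC
are supported behind the same contract through MDAnalysis readers.

Parsing rules for crystal files are deterministic: alternate-location
indicators keep the highest-occupancy copy (tie -> first encountered), and
insertion codes are part of the residue key.  Hydrogens are optional;
downstream modules fall back to heavy-atom criteria when none are present.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, TopologyError
from .systems import AtomRecord, MolecularSystem, Trajectory

#: Frame spacing assumed when a trajectory file carries no time information:
#: 100 ps per saved frame, i.e. 2000 frames per 200 ns production run.
DEFAULT_FRAME_INTERVAL_NS = 0.1

_PDB_COORD_SLICES = ((30, 38), (38, 46), (46, 54))


def _infer_element(atom_name: str, residue_name: str) -> str:
    """Best-effort element from a PDB atom name when columns 77-78 are blank."""
    name = atom_name.strip()
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "C"
    two = stripped[:2].upper()
    # Ion residues named after their element (ZN, NA, CL, MG ...)
    if residue_name.strip().upper() == two:
        return two
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray,
                                                      str, float]:
    """Parse one ATOM/HETATM line -> (record, xyz, altloc, occupancy)."""
    line = line.rstrip("\n").ljust(80)
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # repaired below; some writers overflow the serial field
    name = line[12:16].strip()
    altloc = line[16].strip()
    resname = line[17:20].strip()
    chain = line[21].strip() or " "
    try:
        resnum = int(line[22:26])
    except ValueError as exc:
        raise FormatError(
            f"line {lineno}: unreadable residue number field "
            f"{line[22:26]!r}") from exc
    icode = line[26].strip()
    xyz = np.empty(3)
    for k, (a, b) in enumerate(_PDB_COORD_SLICES):
        field = line[a:b]
        try:
            xyz[k] = float(field)
        except ValueError as exc:
            raise FormatError(
                f"line {lineno}: non-numeric coordinate field "
                f"{field.strip()!r}") from exc
    try:
        occupancy = float(line[54:60]) if line[54:60].strip() else 1.0
    except ValueError:
        occupancy = 1.0
    element = line[76:78].strip() or _infer_element(name, resname)
    record = AtomRecord(
        atom_id=serial if serial > 0 else lineno,
        atom_name=name,
        element=element,
        residue_name=resname,
        residue_number=resnum,
        chain_id=chain,
        is_hetero=line.startswith("HETATM"),
        residue_icode=icode,
    )
    return record, xyz, altloc, occupancy


def _filter_altlocs(parsed: list[tuple[AtomRecord, np.ndarray, str, float]]
                    ) -> list[tuple[AtomRecord, np.ndarray]]:
    """Keep the highest-occupancy alternate location per atom site
    (ties keep the first encountered)."""
    best: dict[tuple, int] = {}
    for i, (rec, _xyz, altloc, occ) in enumerate(parsed):
        key = (rec.chain_id, rec.residue_number, rec.residue_icode,
               rec.atom_name)
        if altloc == "":
            best.setdefault(key, i)
            continue
        if key not in best:
            best[key] = i
        else:
            prev = parsed[best[key]]
            if occ > prev[3]:
                best[key] = i
    keep = sorted(best.values())
    return [(parsed[i][0], parsed[i][1]) for i in keep]


def _parse_models(path: Path) -> list[list[tuple[AtomRecord, np.ndarray]]]:
    """All coordinate models of a PDB file, altloc-filtered."""
    models: list[list] = []
    current: list = []
    saw_model_kw = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model_kw = True
                if current:
                    models.append(current)
                    current = []
            elif rec == "ENDMDL":
                models.append(current)
                current = []
            elif rec in ("ATOM", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
            elif rec == "END" and not saw_model_kw:
                break
    if current:
        models.append(current)
    return [_filter_altlocs(m) for m in models if m]


def read_structure(path: str | Path, dialect: str = "pdb") -> MolecularSystem:
    """Read a structure file into a :class:`MolecularSystem`.

    Multi-model files yield the first model as the reference coordinates.
    HETATM records are flagged ``is_hetero``.  Raises :class:`FormatError`
    naming the offending line for malformed coordinate fields, and for files
    without any ATOM/HETATM record.
    """
    if dialect != "pdb":
        raise FormatError(f"unsupported structure dialect {dialect!r}")
    path = Path(path)
    models = _parse_models(path)
    if not models:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    atoms = [rec for rec, _ in models[0]]
    coords = np.array([xyz for _, xyz in models[0]])
    # Repair duplicate serials (seen in concatenated files) deterministically.
    if len({a.atom_id for a in atoms}) != len(atoms):
        atoms = [AtomRecord(i + 1, a.atom_name, a.element, a.residue_name,
                            a.residue_number, a.chain_id, a.is_hetero,
                            a.residue_icode) for i, a in enumerate(atoms)]
    return MolecularSystem(atoms, coords)


def read_trajectory(path: str | Path, system: MolecularSystem,
                    dialect: str = "multi-model-pdb",
                    frame_interval_ns: float | None = None) -> Trajectory:
    """Read a coordinate trajectory over ``system``'s atoms.

    Dialects: ``multi-model-pdb`` (canonical, plain text), ``dcd`` and
    ``xtc`` (via MDAnalysis).  ``frame_times`` come from the file header
    where available, otherwise frames are spaced ``frame_interval_ns``
    apart (default :data:`DEFAULT_FRAME_INTERVAL_NS`).
    """
    path = Path(path)
    if dialect == "multi-model-pdb":
        models = _parse_models(path)
        if not models:
            raise FormatError(f"{path}: no coordinate models found")
        frames = []
        for k, model in enumerate(models):
            if len(model) != system.n_atoms:
                raise TopologyError(
                    f"{path}: model {k + 1} has {len(model)} atoms, system "
                    f"has {system.n_atoms}; recovered {len(frames)} complete "
                    f"frames before the mismatch")
            frames.append(np.array([xyz for _, xyz in model]))
        arr = np.array(frames)
        dt = DEFAULT_FRAME_INTERVAL_NS if frame_interval_ns is None \
            else frame_interval_ns
        times = np.arange(arr.shape[0]) * dt
        return Trajectory(system, arr, times)
    if dialect in ("dcd", "xtc"):
        return _read_binary_trajectory(path, system, dialect,
                                       frame_interval_ns)
    raise FormatError(f"unsupported trajectory dialect {dialect!r}")


def _read_binary_trajectory(path: Path, system: MolecularSystem,
                            dialect: str,
                            frame_interval_ns: float | None) -> Trajectory:
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.XTC import XTCReader

    reader_cls = DCDReader if dialect == "dcd" else XTCReader
    reader = reader_cls(str(path))
    try:
        if reader.n_atoms != system.n_atoms:
            raise TopologyError(
                f"{path}: trajectory has {reader.n_atoms} atoms, system has "
                f"{system.n_atoms}")
        frames, times_ps = [], []
        for ts in reader:
            frames.append(np.array(ts.positions, dtype=float))
            times_ps.append(float(ts.time))
    finally:
        reader.close()
    arr = np.array(frames)
    if frame_interval_ns is not None:
        times = np.arange(arr.shape[0]) * frame_interval_ns
    else:
        times = np.array(times_ps) / 1000.0  # MDAnalysis times are ps
        if np.any(np.diff(times) < 0) or (len(times) > 1
                                          and np.allclose(times, times[0])):
            times = np.arange(arr.shape[0]) * DEFAULT_FRAME_INTERVAL_NS
    return Trajectory(system, arr, times)


def _format_atom_line(rec: AtomRecord, xyz: np.ndarray, serial: int) -> str:
    tag = "HETATM" if rec.is_hetero else "ATOM  "
    name = rec.atom_name
    if len(name) < 4:
        name = f" {name:<3s}"
    else:
        name = f"{name:<4s}"
    return (f"{tag}{serial:5d} {name}{'':1s}{rec.residue_name:>3s} "
            f"{rec.chain_id:1s}{rec.residue_number:4d}{rec.residue_icode:1s}"
            f"   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {rec.element.upper():>2s}")


def write_structure(system: MolecularSystem, path: str | Path,
                    coordinates: np.ndarray | None = None) -> None:
    """Write a system (reference coordinates by default) as a PDB file."""
    coords = system.reference_coordinates if coordinates is None else coordinates
    lines = [_format_atom_line(a, coords[i], i + 1)
             for i, a in enumerate(system.atoms)]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    out = []
    for k, frame in enumerate(trajectory.frames):
        out.append(f"MODEL     {k + 1:4d}")
        out.extend(_format_atom_line(a, frame[i], i + 1)
                   for i, a in enumerate(trajectory.system.atoms))
        out.append("ENDMDL")
    out.append("END")
    Path(path).write_text("\n".join(out) + "\n")


def write_table(rows: Sequence[Mapping] | pd.DataFrame, path: str | Path,
                dialect: str = "tsv") -> None:
    """Write homogeneous records as TSV or JSON.

    Numeric fields survive a round trip at 6 significant digits; the column
    order of the first record is preserved.  An empty row set produces a
    header-only TSV / an empty JSON list.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows))
    path = Path(path)
    if dialect == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif dialect == "json":
        records = json.loads(df.to_json(orient="records", double_precision=10))
        path.write_text(json.dumps(records, indent=1) + "\n")
    else:
        raise FormatError(f"unsupported table dialect {dialect!r}")


def read_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if dialect == "tsv":
        return pd.read_csv(path, sep="\t")
    if dialect == "json":
        return pd.DataFrame(json.loads(path.read_text()))
    raise FormatError(f"unsupported table dialect {dialect!r}")
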