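"""Solvent-accessible surface area (Shrake–Rupley) and buried interface area.

SASA is computed by deterministic quadrature: every atom's solvent sphere
(radius = vdW radius + probe radius, probe 1.4 Å by default) is sampled on a
golden-section spiral, and a sample point counts as accessible when it lies
outside every neighbouring atom's solvent sphere.  The spiral is a fixed
point set — no random numbers — so repeated runs are bit-identical, and the
default of 960 points keeps the isolated-sphere quadrature error below 1%.

The buried interface (contact) area between two disjoint atom groups is the
per-side buried SASA,

    A_buried = (SASA(A) + SASA(B) - SASA(A ∪ B)) / 2,

the convention under which the published JUNO–IZUMO1 crystal interfaces
measure 842–910 Å².
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .errors import DomainError
from .systems import MolecularSystem

__all__ = ["vdw_radii_table", "vdw_radii", "sphere_points",
           "shrake_rupley_sasa", "buried_interface_area"]

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960

_RADII_CACHE: dict[str, float] | None = None


def vdw_radii_table() -> dict[str, float]:
    """The packaged element -> vdW radius (Å) table."""
    global _RADII_CACHE
    if _RADII_CACHE is None:
        text = resources.files("hingemd.data").joinpath(
            "vdw_radii.json").read_text()
        raw = json.loads(text)
        _RADII_CACHE = {k.upper(): float(v) for k, v in raw.items()
                        if k != "comment"}
    return _RADII_CACHE


def vdw_radii(elements: list[str] | MolecularSystem) -> np.ndarray:
    """Per-atom vdW radii for a list of elements or a system."""
    if isinstance(elements, MolecularSystem):
        elements = elements.elements
    table = vdw_radii_table()
    default = table["DEFAULT"]
    return np.array([table.get(e.upper(), default) for e in elements])


def sphere_points(n: int) -> np.ndarray:
    """``n`` nearly uniform unit-sphere points on a golden-section spiral.

    Deterministic (no RNG): point k sits at z evenly spaced in (-1, 1) and
    azimuth k times the golden angle.
    """
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       probe: float = DEFAULT_PROBE_RADIUS,
                       n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (Å²).

    Parameters
    ----------
    coords : (n, 3) array, Å
    radii : per-atom vdW radii, Å (all positive)
    probe : probe sphere radius, Å
    n_points : quadrature points per atom (≥ 60)
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise DomainError(f"coords must be (n, 3), got {coords.shape}")
    if radii.shape != (coords.shape[0],):
        raise DomainError("one radius per atom required")
    if np.any(radii <= 0):
        raise DomainError("vdW radii must be positive")
    if probe < 0:
        raise DomainError("probe radius must be non-negative")
    if n_points < 60:
        raise DomainError("n_points must be at least 60")

    n = coords.shape[0]
    solvent_r = radii + probe
    unit = sphere_points(n_points)
    areas = np.empty(n)
    tree = cKDTree(coords)
    max_reach = 2.0 * solvent_r.max()
    neighbor_lists = tree.query_ball_tree(tree, r=max_reach)
    for i in range(n):
        pts = coords[i] + solvent_r[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            d = np.linalg.norm(coords[j] - coords[i])
            if d >= solvent_r[i] + solvent_r[j]:
                continue
            close = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j]) \
                < solvent_r[j] ** 2
            accessible &= ~close
            if not accessible.any():
                break
        areas[i] = accessible.mean() * 4.0 * np.pi * solvent_r[i] ** 2
    return areas


def buried_interface_area(coords: np.ndarray, group_a: np.ndarray,
                          group_b: np.ndarray,
                          radii: np.ndarray,
                          probe: float = DEFAULT_PROBE_RADIUS,
                          n_points: int = DEFAULT_N_POINTS) -> float:
    """Per-side buried SASA between two disjoint atom groups (Å²).

    Returns ``(SASA(A) + SASA(B) - SASA(A ∪ B)) / 2``, clamped at zero
    against quadrature noise.  ``radii`` is the full per-atom radius array
    of the coordinate set; groups index into it.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if group_a.size == 0 or group_b.size == 0:
        raise DomainError("interface groups must be non-empty")
    if np.intersect1d(group_a, group_b).size:
        raise DomainError("interface groups overlap")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    sasa_a = shrake_rupley_sasa(coords[group_a], radii[group_a],
                                probe, n_points).sum()
    sasa_b = shrake_rupley_sasa(coords[group_b], radii[group_b],
                                probe, n_points).sum()
    both = np.concatenate([group_a, group_b])
    sasa_ab = shrake_rupley_sasa(coords[both], radii[both],
                                 probe, n_points).sum()
    return max(0.0, float(sasa_a + sasa_b - sasa_ab) / 2.0)
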