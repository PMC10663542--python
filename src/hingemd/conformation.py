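"""Conformational state statistics from per-frame hinge angles.

A frame is labelled ``boomerang`` when its hinge angle is below the
threshold (140° by default) and ``straight`` otherwise — a frame exactly at
the threshold is labelled straight, so that every frame gets a
deterministic label.  From the label series the module derives state
occupancies, the shift count (raw frame-to-frame label changes, no
smoothing), and dwell-length statistics, and offers an unbiased
agglomerative clustering of frames by pairwise Cα RMSD as an independent
check on the threshold classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import DomainError
from .geometry import DomainDefinition, hinge_angle, kabsch
from .systems import Trajectory

__all__ = ["StateTimeline", "DEFAULT_HINGE_THRESHOLD",
           "classify_conformations", "count_shifts", "occupancy_and_dwell",
           "cluster_states", "hinge_angle_series", "angle_histogram"]

DEFAULT_HINGE_THRESHOLD = 140.0
STATE_NAMES = ("straight", "boomerang")


@dataclass
class StateTimeline:
    """Per-frame hinge angles and conformational labels with statistics.

    ``labels`` holds 0 for straight and 1 for boomerang.  Occupancies sum
    to one; ``n_shifts`` counts frame-to-frame label changes; ``dwells``
    are maximal constant-label runs as (state, length-in-frames).
    """

    angles: np.ndarray
    labels: np.ndarray
    threshold: float
    frame_times: np.ndarray

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)

    @property
    def occupancy(self) -> dict[str, float]:
        boom = float(np.mean(self.labels == 1))
        return {"straight": 1.0 - boom, "boomerang": boom}

    @property
    def n_shifts(self) -> int:
        return count_shifts(self)

    @property
    def dwells(self) -> list[tuple[str, int]]:
        out: list[tuple[str, int]] = []
        labels = self.labels
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                out.append((STATE_NAMES[int(labels[start])], i - start))
                start = i
        return out


def hinge_angle_series(trajectory: Trajectory,
                       domains: tuple[DomainDefinition, DomainDefinition,
                                      DomainDefinition],
                       mass_weighted: bool = True) -> np.ndarray:
    """Hinge angle (degrees) for every frame, vectorized over frames."""
    system = trajectory.system
    masses = system.masses
    coms = []
    for dom in domains:
        idx = dom.atom_indices(system, heavy_only=True)
        if idx.size == 0:
            raise DomainError(f"domain {dom.label!r} selects no atoms")
        w = masses[idx] if mass_weighted else np.ones(idx.size)
        w = w / w.sum()
        coms.append(np.einsum("fij,i->fj", trajectory.frames[:, idx, :], w))
    v1 = coms[0] - coms[1]
    v2 = coms[2] - coms[1]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 < 1e-9) or np.any(n2 < 1e-9):
        raise DomainError("degenerate geometry: coincident domain COMs")
    cosang = np.clip(np.einsum("fi,fi->f", v1, v2) / (n1 * n2), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def classify_conformations(trajectory: Trajectory,
                           domains: tuple[DomainDefinition, DomainDefinition,
                                          DomainDefinition],
                           threshold: float = DEFAULT_HINGE_THRESHOLD
                           ) -> StateTimeline:
    """Label every frame straight/boomerang by its hinge angle.

    Boomerang iff angle < threshold; an angle exactly at the threshold is
    straight (deterministic tie rule).  Domain overlap and emptiness are
    validated through the same checks as :func:`hingemd.geometry.hinge_angle`.
    """
    # validate once on the first frame (overlap/empty/degenerate checks)
    hinge_angle(trajectory.frames[0], trajectory.system, tuple(domains))
    angles = hinge_angle_series(trajectory, tuple(domains))
    labels = (angles < threshold).astype(np.int8)
    return StateTimeline(angles, labels, threshold, trajectory.frame_times)


def count_shifts(timeline: StateTimeline) -> int:
    """Raw frame-to-frame label changes (no hysteresis or debouncing);
    a single-frame timeline has zero shifts."""
    labels = timeline.labels
    return int(np.count_nonzero(labels[1:] != labels[:-1]))


def occupancy_and_dwell(timeline: StateTimeline,
                        debounce_window: int = 0) -> dict:
    """State occupancies, dwell-length distribution and mean dwell lengths.

    ``debounce_window`` > 0 first removes dwells shorter than the window by
    merging them into the previous state (a robustness option; the default
    keeps the raw label series so that shift counts stay raw label
    changes).
    """
    labels = timeline.labels.copy()
    if debounce_window > 0:
        changed = True
        while changed:
            changed = False
            tl = StateTimeline(timeline.angles, labels, timeline.threshold,
                               timeline.frame_times)
            pos = 0
            for state, length in tl.dwells:
                if length < debounce_window and pos > 0:
                    labels[pos:pos + length] = labels[pos - 1]
                    changed = True
                    break
                pos += length
    tl = StateTimeline(timeline.angles, labels, timeline.threshold,
                       timeline.frame_times)
    dwells = tl.dwells
    per_state: dict[str, list[int]] = {"straight": [], "boomerang": []}
    for state, length in dwells:
        per_state[state].append(length)
    return {
        "occupancy": tl.occupancy,
        "dwell_lengths": dwells,
        "mean_dwell": {s: (float(np.mean(v)) if v else 0.0)
                       for s, v in per_state.items()},
        "n_shifts": tl.n_shifts,
    }


def angle_histogram(timeline: StateTimeline,
                    bin_width: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of hinge angles with fixed-width bins (1° by default)."""
    lo = np.floor(timeline.angles.min() / bin_width) * bin_width
    hi = np.ceil(timeline.angles.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(timeline.angles, bins=edges)
    return counts, edges


def cluster_states(trajectory: Trajectory, selection: np.ndarray,
                   k: int = 3, linkage_method: str = "average",
                   domains: tuple[DomainDefinition, ...] | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased clustering of frames by pairwise superposed RMSD.

    Computes the all-against-all RMSD matrix over the selected atoms
    (each pair superposed first), clusters it agglomeratively with the
    given linkage cut at ``k`` clusters, and returns (per-frame labels,
    medoid frame indices).  The medoid of a cluster is the frame minimizing
    the summed distance within its cluster (ties -> earliest frame).

    Cluster ids are ordered by medoid hinge angle when ``domains`` is
    given (0 = most bent ... k-1 = straightest), otherwise by first
    occurrence in the trajectory.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size < 3:
        raise DomainError("clustering needs at least 3 selected atoms")
    n = trajectory.n_frames
    if k < 1 or k > n:
        raise DomainError(f"cluster count {k} outside [1, {n}]")
    sub = trajectory.frames[:, selection, :]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            t = kabsch(sub[j], sub[i])
            moved = t.apply(sub[j])
            dist[i, j] = dist[j, i] = float(
                np.sqrt(((moved - sub[i]) ** 2).sum(axis=1).mean()))
    if k == 1:
        raw = np.zeros(n, dtype=int)
    elif n == k:
        raw = np.arange(n)
    else:
        Z = linkage(squareform(dist, checks=False), method=linkage_method)
        raw = fcluster(Z, t=k, criterion="maxclust") - 1
    medoids = {}
    for c in np.unique(raw):
        members = np.flatnonzero(raw == c)
        sums = dist[np.ix_(members, members)].sum(axis=1)
        medoids[c] = int(members[int(np.argmin(sums))])
    if domains is not None:
        angle_of = {c: hinge_angle(trajectory.frames[m], trajectory.system,
                                   tuple(domains))
                    for c, m in medoids.items()}
        order = sorted(medoids, key=lambda c: angle_of[c])
    else:
        first_seen = {c: int(np.flatnonzero(raw == c)[0])
                      for c in np.unique(raw)}
        order = sorted(medoids, key=lambda c: first_seen[c])
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in raw])
    medoid_frames = np.array([medoids[old] for old in order])
    return labels, medoid_frames
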