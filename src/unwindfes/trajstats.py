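"""Geometric trajectory statistics.

Hydrogen-bond occupancy under a distance + angle criterion, distance time
series and distributions, leader-algorithm RMSD clustering, and
secondary-structure occupancy, each aggregated across replicas as
mean ± standard deviation.

The hydrogen-bond angle cutoff is read as the deviation of the D-H...A angle
from linearity: a frame is bonded when some donor-acceptor pair has
donor-acceptor distance <= 3.2 Å and D-H...A >= 150° (both boundaries
inclusive, defaults per the adopted criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cvs import SegmentLibrary, alpha_rmsd, antibeta_rmsd
from .frames import Frame, Trajectory
from .geometry import kabsch_rmsd


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond definition."""

    distance_cutoff: float = 3.2  # Å, donor-acceptor
    angle_cutoff: float = 30.0  # degrees deviation from linearity of D-H...A

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.angle_cutoff > 180:
            raise ValueError("angle cutoff cannot exceed 180 degrees")


@dataclass
class OccupancyResult:
    """Per-replica occupancy fractions with mean ± sd across replicas."""

    per_replica: list[float]
    mean: float
    sd: float

    @classmethod
    def from_fractions(cls, fractions: list[float]) -> "OccupancyResult":
        arr = np.asarray(fractions, dtype=float)
        return cls(
            per_replica=list(map(float, arr)),
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=0)),
        )


@dataclass
class ClusterConfig:
    """Leader-algorithm clustering settings."""

    rmsd_cutoff: float = 2.0  # Å
    selection: np.ndarray | None = None  # atom indices; all atoms if None

    def __post_init__(self) -> None:
        if self.rmsd_cutoff <= 0:
            raise ValueError("rmsd_cutoff must be positive")


def _angle_deviation(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """Deviation from linearity (degrees) of the D-H...A angle."""
    v1 = d - h
    v2 = a - h
    cos = np.clip(
        (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0
    )
    return 180.0 - float(np.degrees(np.arccos(cos)))


#: Numerical slack making the inclusive boundary well defined under
#: floating point (a pair constructed exactly at the cutoff stays bonded).
_BOUNDARY_TOL = 1e-9


def frame_has_hbond(
    frame: Frame,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    criterion: HBondCriterion | None = None,
) -> bool:
    """True if any donor (D, H) / acceptor pair satisfies the criterion.

    Boundaries are inclusive: distance == cutoff and deviation == cutoff
    both count as bonded (to within 1e-9 numerical tolerance).
    """
    if criterion is None:
        criterion = HBondCriterion()
    for d_idx, h_idx in donors:
        d = frame.coords[d_idx]
        h = frame.coords[h_idx]
        for a_idx in acceptors:
            a = frame.coords[a_idx]
            if np.linalg.norm(d - a) <= criterion.distance_cutoff + _BOUNDARY_TOL and (
                _angle_deviation(d, h, a) <= criterion.angle_cutoff + _BOUNDARY_TOL
            ):
                return True
    return False


def hbond_occupancy(
    trajectories: list[Trajectory] | Trajectory,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    criterion: HBondCriterion | None = None,
) -> OccupancyResult:
    """Fraction of frames with a hydrogen bond, per replica and aggregated."""
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if criterion is None:
        criterion = HBondCriterion()
    for t in trajectories:
        n_atoms = t.topology.n_atoms
        for d_idx, h_idx in donors:
            if not (0 <= d_idx < n_atoms and 0 <= h_idx < n_atoms):
                raise ValueError(f"donor pair ({d_idx}, {h_idx}) out of range")
            if t.topology.atom_names[h_idx][:1] != "H":
                raise ValueError(
                    f"donor hydrogen index {h_idx} is atom "
                    f"{t.topology.atom_names[h_idx]!r}, not a hydrogen"
                )
    fractions = []
    for t in trajectories:
        bonded = sum(
            frame_has_hbond(f, donors, acceptors, criterion) for f in t
        )
        fractions.append(bonded / t.n_frames)
    return OccupancyResult.from_fractions(fractions)


def distance_series(
    traj: Trajectory,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    mode: str = "atom-atom",
    masses: np.ndarray | None = None,
    n_bins: int = 50,
) -> dict:
    """Per-frame distance between two selections, plus a normalized histogram.

    ``mode`` "atom-atom" takes single-atom selections; "com-com" uses the
    (mass-weighted if masses are given, else geometric) centers of mass.
    Returns a dict with the series, mean, sd, and histogram (density).
    """
    sel_a = np.atleast_1d(np.asarray(sel_a, dtype=int))
    sel_b = np.atleast_1d(np.asarray(sel_b, dtype=int))
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("empty selection")
    if mode == "atom-atom":
        if len(sel_a) != 1 or len(sel_b) != 1:
            raise ValueError("atom-atom mode needs single-atom selections")
        pa = traj.coords[:, sel_a[0]]
        pb = traj.coords[:, sel_b[0]]
    elif mode == "com-com":
        def com(sel):
            sub = traj.coords[:, sel]
            if masses is not None:
                w = np.asarray(masses, dtype=float)[sel]
                return (sub * w[None, :, None]).sum(axis=1) / w.sum()
            return sub.mean(axis=1)
        pa, pb = com(sel_a), com(sel_b)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    series = np.linalg.norm(pa - pb, axis=1)
    hist, edges = np.histogram(series, bins=n_bins, density=True)
    return {
        "series": series,
        "times": traj.times,
        "mean": float(series.mean()),
        "sd": float(series.std(ddof=0)),
        "hist": hist,
        "hist_edges": edges,
    }


def cluster_frames(
    traj: Trajectory, config: ClusterConfig | None = None
) -> dict:
    """Leader-algorithm RMSD clustering of a trajectory.

    The first frame seeds cluster 1; each subsequent frame joins the first
    existing centroid whose superposed RMSD is <= the cutoff, otherwise it
    seeds a new cluster.  Deterministic given the frame order.  Returns
    labels (0-based), centroid frame indices, and populations.
    """
    if config is None:
        config = ClusterConfig()
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")
    sel = (
        np.arange(traj.topology.n_atoms)
        if config.selection is None
        else np.asarray(config.selection, dtype=int)
    )
    if len(sel) < 3:
        raise ValueError("degenerate superposition: selection has < 3 atoms")
    coords = traj.coords[:, sel]
    centroids: list[int] = []
    labels = np.empty(traj.n_frames, dtype=int)
    for i in range(traj.n_frames):
        assigned = -1
        for c, ci in enumerate(centroids):
            if kabsch_rmsd(coords[i], coords[ci]) <= config.rmsd_cutoff:
                assigned = c
                break
        if assigned < 0:
            centroids.append(i)
            assigned = len(centroids) - 1
        labels[i] = assigned
    populations = np.bincount(labels, minlength=len(centroids))
    return {
        "labels": labels,
        "centroids": np.array(centroids),
        "populations": populations,
    }


def ss_occupancy(
    trajectories: list[Trajectory] | Trajectory,
    kind: str,
    threshold: float,
    residue_window: tuple[int, int] | None = None,
    segments: list[tuple[str, int, int]] | None = None,
    library: SegmentLibrary | None = None,
    chain_id: str = "A",
) -> OccupancyResult:
    """Fraction of frames whose secondary-structure score meets a threshold.

    ``kind`` is "alpha" (uses ``residue_window``) or "antibeta" (uses
    ``segments``); a frame counts when its score S >= ``threshold``.
    Aggregated as mean ± sd across replicas.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if kind == "alpha":
        if residue_window is None:
            raise ValueError("alpha occupancy needs a residue_window")
        lib = library or SegmentLibrary.alpha()
        def score(frame: Frame) -> float:
            return alpha_rmsd(frame, residue_window, lib, chain_id=chain_id).S
    elif kind == "antibeta":
        if segments is None:
            raise ValueError("antibeta occupancy needs segments")
        lib = library or SegmentLibrary.antibeta()
        def score(frame: Frame) -> float:
            return antibeta_rmsd(frame, segments, lib).S
    else:
        raise ValueError(f"unknown secondary-structure kind {kind!r}")
    fractions = []
    for t in trajectories:
        hits = sum(score(f) >= threshold for f in t)
        fractions.append(hits / t.n_frames)
    return OccupancyResult.from_fractions(fractions)
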