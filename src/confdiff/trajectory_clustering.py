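"""Trajectory frame partitioning, RMSD matrices and threshold clustering.

Post-processing protocol for a coordinate trajectory: snapshots recorded at
fixed intervals are grouped into consecutive frames, a symmetric
main-chain RMSD matrix over frames is built, frames closer than a cutoff
(2 Å by default, strict inequality) are merged into clusters by
single-linkage transitive closure, and each cluster is represented by its
medoid — the member with minimal summed RMSD to the other members.

One bookkeeping subtlety is handled explicitly: a trajectory of 1001
snapshots split into frames of up to 10 consecutive snapshots yields
``ceil(1001/10) = 101`` frames with a short final frame; frame count is
always ``ceil(n/size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, floor
from typing import Literal, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .backbone_geometry import coordinate_rmsd, kabsch_superpose, apply_superposition
from .structure_io import StructureModel, backbone_atoms

__all__ = [
    "Trajectory",
    "Frame",
    "ClusterSet",
    "count_snapshots",
    "partition_snapshots",
    "frame_coordinates",
    "frame_rmsd_matrix",
    "threshold_cluster",
    "cluster_representative",
    "cluster_trajectory",
]


@dataclass
class Trajectory:
    """Ordered coordinate snapshots sharing one topology."""

    snapshots: list[StructureModel]
    time_spacing_ns: float = 1.0

    def __post_init__(self) -> None:
        if not self.snapshots:
            raise ValueError("empty trajectory")
        n0 = self.snapshots[0].n_atoms
        for i, s in enumerate(self.snapshots):
            if s.n_atoms != n0:
                raise ValueError(
                    f"topology mismatch: snapshot {i + 1} has {s.n_atoms} atoms, expected {n0}"
                )

    def __len__(self) -> int:
        return len(self.snapshots)


@dataclass
class Frame:
    """A consecutive block of snapshots with one representative coordinate set."""

    index: int  # 1-based
    members: list[int]  # 1-based snapshot indices, consecutive
    representative: np.ndarray | None = None  # (n_atoms, 3)


@dataclass
class ClusterSet:
    """Disjoint partition of frame indices with a medoid per cluster."""

    clusters: list[list[int]]  # frame indices, each frame in exactly one cluster
    representatives: list[int] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self, n_frames: int) -> np.ndarray:
        lab = np.full(n_frames, -1, dtype=int)
        for ci, members in enumerate(self.clusters):
            for f in members:
                lab[f - 1] = ci
        return lab


def count_snapshots(
    duration_ns: float, interval_ns: float, include_time_zero: bool = True
) -> int:
    """Number of snapshots a run of ``duration_ns`` records every ``interval_ns``.

    ``floor(duration/interval)`` plus one for the t=0 coordinates when
    included — a 1 μs run sampled every 1 ns including t=0 yields 1001.
    """
    if duration_ns <= 0 or interval_ns <= 0:
        raise ValueError("duration and interval must be positive")
    return floor(duration_ns / interval_ns) + (1 if include_time_zero else 0)


def partition_snapshots(n_snapshots: int, frame_size: int) -> list[Frame]:
    """Split snapshot indices 1..n into consecutive frames of ``frame_size``.

    The final frame holds the remainder, so the frame count is
    ``ceil(n/size)`` — 1001 snapshots at size 10 give 101 frames.
    """
    if n_snapshots < 1 or frame_size < 1:
        raise ValueError("n_snapshots and frame_size must be >= 1")
    frames = []
    for fi in range(ceil(n_snapshots / frame_size)):
        start = fi * frame_size + 1
        stop = min(start + frame_size, n_snapshots + 1)
        frames.append(Frame(index=fi + 1, members=list(range(start, stop))))
    return frames


def frame_coordinates(
    traj: Trajectory,
    frames: Sequence[Frame],
    atom_set: str = "N_CA_C",
    mode: Literal["mean", "central"] = "mean",
) -> list[Frame]:
    """Attach representative main-chain coordinates to each frame.

    ``mode="mean"`` (default) superposes every member snapshot onto the
    frame's first snapshot and averages the coordinates; ``"central"``
    takes the middle member snapshot verbatim.
    """
    coords = []
    for s in traj.snapshots:
        xyz, _ = backbone_atoms(s, atom_set)
        coords.append(xyz)
    n0 = coords[0].shape
    if any(c.shape != n0 for c in coords):
        raise ValueError("topology mismatch: snapshots expose different main-chain atoms")
    out = []
    for f in frames:
        member_xyz = [coords[i - 1] for i in f.members]
        if mode == "central":
            rep = member_xyz[len(member_xyz) // 2]
        elif mode == "mean":
            ref = member_xyz[0]
            aligned = [ref]
            for xyz in member_xyz[1:]:
                sup = kabsch_superpose(xyz, ref)
                aligned.append(apply_superposition(xyz, sup))
            rep = np.mean(aligned, axis=0)
        else:
            raise ValueError(f"unknown representative mode {mode!r}")
        out.append(Frame(index=f.index, members=list(f.members), representative=rep))
    return out


def frame_rmsd_matrix(
    frames: Sequence[Frame], superpose: bool = True
) -> np.ndarray:
    """Symmetric matrix of pairwise frame RMSDs (Kabsch-minimised by default)."""
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    reps = []
    for f in frames:
        if f.representative is None:
            raise ValueError(f"frame {f.index} has no representative coordinates")
        reps.append(np.asarray(f.representative, dtype=float))
    if any(r.shape != reps[0].shape for r in reps):
        raise ValueError("topology mismatch between frame representatives")
    n = len(reps)
    m = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = coordinate_rmsd(reps[i], reps[j], superpose=superpose)
    return m


def threshold_cluster(m: np.ndarray, threshold: float = 2.0) -> ClusterSet:
    """Single-linkage clustering: connected components of the RMSD-< threshold graph.

    Frames i and j are joined whenever ``m[i, j] < threshold`` (strict),
    and membership is closed transitively, so a 1.5 Å / 1.5 Å chain pulls
    a 3 Å pair into one cluster.  Representatives are the medoids.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("RMSD matrix must be square")
    n = m.shape[0]
    adj = csr_matrix((m < threshold).astype(int))
    n_comp, labels = connected_components(adj, directed=False)
    clusters: list[list[int]] = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        clusters[lab].append(i + 1)
    # deterministic order: by smallest member frame index
    clusters.sort(key=lambda c: c[0])
    reps = [cluster_representative(c, m) for c in clusters]
    return ClusterSet(clusters=clusters, representatives=reps)


def cluster_representative(cluster: Sequence[int], m: np.ndarray) -> int:
    """Medoid of a cluster: member with minimal summed RMSD to the others.

    Ties are broken by the lowest frame index; a singleton represents
    itself.
    """
    members = sorted(cluster)
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return members[0]
    best = None
    best_sum = None
    for f in members:
        s = sum(m[f - 1, g - 1] for g in members if g != f)
        if best_sum is None or s < best_sum - 1e-12:
            best, best_sum = f, s
    return best


def cluster_trajectory(
    traj: Trajectory,
    frame_size: int = 10,
    threshold: float = 2.0,
    atom_set: str = "N_CA_C",
    mode: Literal["mean", "central"] = "mean",
    superpose: bool = True,
) -> tuple[list[Frame], np.ndarray, ClusterSet]:
    """Full protocol: partition → frame coordinates → RMSD matrix → clusters."""
    frames = partition_snapshots(len(traj), frame_size)
    frames = frame_coordinates(traj, frames, atom_set=atom_set, mode=mode)
    if len(frames) == 1:
        return frames, np.zeros((1, 1)), ClusterSet(clusters=[[1]], representatives=[1])
    m = frame_rmsd_matrix(frames, superpose=superpose)
    return frames, m, threshold_cluster(m, threshold)
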