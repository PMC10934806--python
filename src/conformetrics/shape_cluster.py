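"""RMSD clustering, U-shape classification, and contact maps.

Clustering is the deterministic GROMOS greedy rule: repeatedly take the
frame with the most neighbours within the cutoff as a cluster centre,
assign its neighbours, remove them, repeat.  The U-shape test is a
three-condition geometric operationalisation (two arm windows whose
best-fit axes point in opposite directions, a maximum inter-arm
distance, and a chain-direction reversal inside the turn window); every
threshold is configurable and echoed into reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import Selection, Trajectory, select

__all__ = [
    "ClusterSet",
    "UShapeParams",
    "UShapeReport",
    "ContactMap",
    "cluster",
    "classify_u",
    "u_percentage",
    "contact_map",
]


@dataclass
class ClusterSet:
    """Partition of frames with populations and representative frames."""

    frame_cluster: np.ndarray  # (n_frames,) cluster id per frame
    populations: list[int]  # frames per cluster, cluster id order
    representatives: list[int]  # frame index per cluster

    @property
    def n_frames(self) -> int:
        return len(self.frame_cluster)

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def population_pct(self, cid: int) -> float:
        return 100.0 * self.populations[cid] / self.n_frames


@dataclass(frozen=True)
class UShapeParams:
    """Thresholds of the U-shape test (author residue numbering)."""

    arm1: tuple[int, int] = (12, 21)
    arm2: tuple[int, int] = (28, 39)
    turn: tuple[int, int] = (22, 28)
    min_arm_angle: float = 120.0  # degrees between arm chain directions
    max_arm_distance: float = 12.0  # Angstrom, min inter-arm CA distance


@dataclass(frozen=True)
class UShapeReport:
    is_u: bool
    arm1: tuple[int, int]
    arm2: tuple[int, int]
    turn: tuple[int, int]
    arm_angle: float  # degrees in [0, 180]
    min_arm_distance: float  # Angstrom
    has_reversal: bool


def cluster(rmsd_matrix: np.ndarray, cutoff: float) -> ClusterSet:
    """GROMOS greedy neighbour-count clustering of an RMSD matrix.

    Ties in neighbour count resolve to the lowest frame index; the
    representative of each cluster is the member minimising mean RMSD
    to the other members (ties again to the lowest index).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    m = np.asarray(rmsd_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("rmsd matrix must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("rmsd matrix must be symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=1e-8):
        raise ValueError("rmsd matrix must have zero diagonal")

    n = m.shape[0]
    remaining = np.ones(n, dtype=bool)
    assignment = np.full(n, -1, dtype=int)
    populations: list[int] = []
    representatives: list[int] = []
    neighbours = m <= cutoff

    cid = 0
    while remaining.any():
        counts = (neighbours & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        centre = int(np.argmax(counts))  # argmax takes lowest index on ties
        members = np.where(neighbours[centre] & remaining)[0]
        assignment[members] = cid
        remaining[members] = False
        if len(members) == 1:
            rep = int(members[0])
        else:
            sub = m[np.ix_(members, members)]
            mean_rmsd = sub.sum(axis=1) / (len(members) - 1)
            rep = int(members[np.argmin(mean_rmsd)])
        populations.append(len(members))
        representatives.append(rep)
        cid += 1

    return ClusterSet(
        frame_cluster=assignment,
        populations=populations,
        representatives=representatives,
    )


def _ca_positions(
    traj: Trajectory, frame_index: int, res_range: tuple[int, int]
) -> np.ndarray:
    sel = select(traj, res_range=res_range, atom_names={"CA"})
    expected = res_range[1] - res_range[0] + 1
    if len(sel) != expected:
        raise ValueError(
            f"missing CA atoms in residues {res_range[0]}-{res_range[1]}"
        )
    return traj.coords[frame_index, sel.as_array()]


def _chain_axis(ca: np.ndarray) -> np.ndarray:
    """Best-fit line direction of a CA window, oriented along the chain."""
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis


def classify_u(
    traj: Trajectory,
    frame_index: int,
    params: UShapeParams = UShapeParams(),
) -> UShapeReport:
    """Three-condition U-shape test on one monomer frame.

    is_u is true iff (a) the chain-oriented best-fit axes of the two arm
    windows differ by at least ``min_arm_angle`` degrees, (b) the
    minimum inter-arm CA distance is at most ``max_arm_distance``, and
    (c) the turn window contains a sign change of the step projections
    onto the arm-1 axis (the chain's direction reversal).
    """
    if params.arm1[1] >= params.arm2[0]:
        raise ValueError("arm windows must be disjoint and ordered")
    ca1 = _ca_positions(traj, frame_index, params.arm1)
    ca2 = _ca_positions(traj, frame_index, params.arm2)

    axis1 = _chain_axis(ca1)
    axis2 = _chain_axis(ca2)
    cosang = np.clip(np.dot(axis1, axis2), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))

    diff = ca1[:, None, :] - ca2[None, :, :]
    min_dist = float(np.sqrt(np.einsum("ijk,ijk->ij", diff, diff).min()))

    turn_ca = _ca_positions(traj, frame_index, params.turn)
    steps = np.diff(turn_ca, axis=0) @ axis1
    has_reversal = bool((steps > 0).any() and (steps < 0).any())

    is_u = (
        angle >= params.min_arm_angle
        and min_dist <= params.max_arm_distance
        and has_reversal
    )
    return UShapeReport(
        is_u=is_u,
        arm1=params.arm1,
        arm2=params.arm2,
        turn=params.turn,
        arm_angle=angle,
        min_arm_distance=min_dist,
        has_reversal=has_reversal,
    )


def u_percentage(
    clusterset: ClusterSet,
    traj: Trajectory,
    params: UShapeParams = UShapeParams(),
    per_frame: bool = False,
) -> float:
    """Population-weighted U-shape percentage.

    Default mode classifies each cluster representative and sums the
    population percentages of U clusters; ``per_frame`` classifies every
    frame instead.
    """
    if per_frame:
        flags = [
            classify_u(traj, f, params).is_u for f in range(traj.n_frames)
        ]
        return 100.0 * float(np.mean(flags))
    total = 0.0
    for cid in range(clusterset.n_clusters):
        rep = clusterset.representatives[cid]
        if classify_u(traj, rep, params).is_u:
            total += clusterset.population_pct(cid)
    return total


@dataclass
class ContactMap:
    """Symmetric residue-residue contact frequency matrix in [0, 1]."""

    frequencies: np.ndarray
    res_seqs: list[int]
    cutoff: float


def contact_map(
    traj: Trajectory,
    sel: Selection | None = None,
    cutoff: float = 8.0,
) -> ContactMap:
    """Fraction of frames with CA(i)-CA(j) distance within the cutoff."""
    if sel is None:
        sel = select(traj, atom_names={"CA"})
    if len(sel) == 0:
        raise ValueError("empty selection")
    idx = sel.as_array()
    res_seqs = [traj.topology[i].res_seq for i in sel.indices]
    n = len(idx)
    acc = np.zeros((n, n), dtype=float)
    for f in range(traj.n_frames):
        ca = traj.coords[f, idx]
        diff = ca[:, None, :] - ca[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        acc += (dist <= cutoff).astype(float)
    acc /= traj.n_frames
    return ContactMap(frequencies=acc, res_seqs=res_seqs, cutoff=cutoff)
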