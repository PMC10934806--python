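"""Backbone secondary-structure assignment and timelines.

Per-residue labels over {H, E, C} are derived from backbone hydrogen
bonds scored with the Kabsch-Sander electrostatic energy.  Amide
hydrogens are always rebuilt from heavy-atom geometry (file hydrogens
are never trusted), so inputs without hydrogens work unchanged.

Class collapse: only the alpha-helix (two consecutive i -> i+4 turns)
maps to H; parallel/antiparallel bridges and their ladders map to E;
everything else — including 3-10 and pi helices — is C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import AtomRecord, Trajectory

__all__ = [
    "SSTimeline",
    "BackboneHBond",
    "HBOND_CUTOFF",
    "KS_COUPLING",
    "backbone_indices",
    "place_amide_hydrogens",
    "ks_hbond_energy",
    "assign_frame",
    "timeline",
]

#: Kabsch-Sander dimensional factor q1*q2*332 (kcal/mol * Angstrom).
KS_COUPLING = 27.888
#: Bonds are recorded when E < this threshold (kcal/mol).
HBOND_CUTOFF = -0.5
#: Distances below this are treated as clashes (energy -> +inf, no bond).
CLASH_GUARD = 0.5

_NH_LENGTH = 1.00


@dataclass(frozen=True)
class BackboneHBond:
    donor: int  # residue array index (donor N-H)
    acceptor: int  # residue array index (acceptor C=O)
    energy: float


@dataclass
class SSTimeline:
    """Residue x frame label matrix over {H, E, C} plus content percentages."""

    labels: np.ndarray  # (n_residues, n_frames) of 'H'/'E'/'C'
    res_seqs: list[int]

    def content(self, label: str) -> float:
        """Pooled residue-frame percentage of one class."""
        return 100.0 * float(np.mean(self.labels == label))

    def per_frame_content(self, label: str) -> np.ndarray:
        return 100.0 * np.mean(self.labels == label, axis=0)

    @property
    def helix_pct(self) -> float:
        return self.content("H")

    @property
    def sheet_pct(self) -> float:
        return self.content("E")

    @property
    def coil_pct(self) -> float:
        return self.content("C")


def backbone_indices(topology: list[AtomRecord]) -> list[dict]:
    """Per-residue dict of backbone atom indices, ordered by topology.

    Returns one entry per residue with keys 'N', 'CA', 'C', 'O' (missing
    atoms absent), plus 'res_seq', 'res_name', 'chain_id'.
    """
    residues: dict[tuple[str, int], dict] = {}
    order: list[tuple[str, int]] = []
    for i, atom in enumerate(topology):
        key = (atom.chain_id, atom.res_seq)
        if key not in residues:
            residues[key] = {
                "res_seq": atom.res_seq,
                "res_name": atom.res_name,
                "chain_id": atom.chain_id,
            }
            order.append(key)
        if atom.name in ("N", "CA", "C", "O"):
            residues[key][atom.name] = i
    return [residues[k] for k in order]


def place_amide_hydrogens(
    coords: np.ndarray, topology: list[AtomRecord]
) -> dict[int, np.ndarray]:
    """Construct backbone amide H positions from heavy-atom geometry.

    H sits 1.00 A from N in the C(i-1)-N-CA plane, opposite the bisector
    of the two N bonds (standard trans-amide construction).  The first
    residue of each chain and prolines get no hydrogen.
    """
    residues = backbone_indices(topology)
    out: dict[int, np.ndarray] = {}
    for i, res in enumerate(residues):
        for name in ("N", "CA", "C", "O"):
            if name not in res:
                raise ValueError(
                    f"residue {res['chain_id']}:{res['res_seq']} missing backbone {name}"
                )
        if i == 0 or residues[i - 1]["chain_id"] != res["chain_id"]:
            continue
        if res["res_name"] == "PRO":
            continue
        n = coords[res["N"]]
        ca = coords[res["CA"]]
        c_prev = coords[residues[i - 1]["C"]]
        u1 = _unit(c_prev - n)
        u2 = _unit(ca - n)
        bisector = u1 + u2
        if np.linalg.norm(bisector) < 1e-6:
            # Degenerate (collinear) geometry: any perpendicular works.
            probe = np.array([1.0, 0.0, 0.0])
            if abs(u2[0]) > 0.9:
                probe = np.array([0.0, 1.0, 0.0])
            direction = _unit(np.cross(u2, probe))
        else:
            direction = -_unit(bisector)
        out[i] = n + _NH_LENGTH * direction
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("degenerate geometry: zero-length bond vector")
    return v / norm


def ks_hbond_energy(
    c: np.ndarray, o: np.ndarray, n: np.ndarray, h: np.ndarray
) -> float:
    """Kabsch-Sander electrostatic H-bond energy in kcal/mol.

    E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN); pairs with any
    interatomic distance under the clash guard score +inf (no bond).
    """
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < CLASH_GUARD:
        return float("inf")
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_matrix(
    coords: np.ndarray, residues: list[dict], hydrogens: dict[int, np.ndarray]
) -> np.ndarray:
    """bonds[i, j] True when C=O of residue i accepts the N-H of residue j."""
    n_res = len(residues)
    bonds = np.zeros((n_res, n_res), dtype=bool)
    # Coarse distance screen on N..O keeps this O(n^2) loop cheap.
    n_pos = np.array([coords[r["N"]] for r in residues])
    o_pos = np.array([coords[r["O"]] for r in residues])
    d_on = np.linalg.norm(o_pos[:, None, :] - n_pos[None, :, :], axis=2)
    for j, h in hydrogens.items():
        res_j = residues[j]
        for i in range(n_res):
            if abs(i - j) < 2 and residues[i]["chain_id"] == res_j["chain_id"]:
                continue
            if d_on[i, j] > 5.2:
                continue
            e = ks_hbond_energy(
                coords[residues[i]["C"]], o_pos[i], n_pos[j], h
            )
            if e < HBOND_CUTOFF:
                bonds[i, j] = True
    return bonds


def assign_frame(coords: np.ndarray, topology: list[AtomRecord]) -> np.ndarray:
    """Assign {H, E, C} per residue for one frame.

    H: residue covered by two consecutive i -> i+4 turns (minimal
    4-helix rule).  E: member of a parallel or antiparallel bridge
    (ladders arise from runs of bridges).  Helix wins on conflict.
    """
    residues = backbone_indices(topology)
    n_res = len(residues)
    labels = np.full(n_res, "C", dtype="U1")
    if n_res < 5:
        return labels

    hydrogens = place_amide_hydrogens(coords, topology)
    hb = _hbond_matrix(coords, residues, hydrogens)

    # 4-turns: C=O of i accepts N-H of i+4 (same chain).
    turn4 = np.zeros(n_res, dtype=bool)
    for i in range(n_res - 4):
        if residues[i]["chain_id"] == residues[i + 4]["chain_id"] and hb[i, i + 4]:
            turn4[i] = True

    is_bridge = np.zeros(n_res, dtype=bool)
    for i in range(1, n_res - 1):
        for j in range(i + 3, n_res - 1):
            parallel = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            antiparallel = (hb[i, j] and hb[j, i]) or (
                hb[i - 1, j + 1] and hb[j - 1, i + 1]
            )
            if parallel or antiparallel:
                is_bridge[i] = is_bridge[j] = True

    labels[is_bridge] = "E"
    for i in range(1, n_res - 4):
        if turn4[i - 1] and turn4[i]:
            labels[i : i + 4] = "H"  # helix precedence over bridge
    return labels


def timeline(traj: Trajectory) -> SSTimeline:
    """Per-frame assignment over the whole trajectory."""
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    residues = backbone_indices(traj.topology)
    labels = np.empty((len(residues), traj.n_frames), dtype="U1")
    for f in range(traj.n_frames):
        labels[:, f] = assign_frame(traj.coords[f], traj.topology)
    return SSTimeline(labels=labels, res_seqs=[r["res_seq"] for r in residues])
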