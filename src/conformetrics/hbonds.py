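"""Geometric hydrogen-bond detection and residue-pair frequency tables.

A bond is recorded when the donor-acceptor distance and the D-H...A
angle both pass configurable cutoffs (defaults 3.5 A / 135 deg, the
common MD-analysis convention).  Frequencies are aggregated per
unordered residue pair: a pair counts once per frame no matter how many
atom-level bonds connect it, and the average frequency (af) of a pair
is the percentage of frames in which it is bonded at least once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .secstruct import place_amide_hydrogens
from .structio import Selection, Trajectory

__all__ = [
    "HBondObservation",
    "HBondFrequencyTable",
    "detect_hbonds",
    "frequencies",
    "turn_contact_filter",
    "default_donors",
    "default_acceptors",
]

DEFAULT_DISTANCE_CUTOFF = 3.5  # Angstrom, donor-acceptor heavy atoms
DEFAULT_ANGLE_CUTOFF = 135.0  # degrees, D-H...A

#: Sidechain donor heavy atoms per residue (backbone N is always a donor).
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}

#: Sidechain acceptor heavy atoms per residue (backbone O is always one).
SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}

#: Pseudo-atom names used by the synthetic generator's scripted contacts.
PSEUDO_DONOR = "ND"
PSEUDO_DONOR_H = "HD"
PSEUDO_ACCEPTOR = "OA"


@dataclass(frozen=True)
class HBondObservation:
    frame_index: int
    donor_res: int
    donor_atom: str
    acceptor_res: int
    acceptor_atom: str
    distance: float
    angle: float


@dataclass
class HBondFrequencyTable:
    """Unordered residue pair (i < j) -> average frequency percent."""

    af: dict[tuple[int, int], float] = field(default_factory=dict)

    def items_sorted(self) -> list[tuple[tuple[int, int], float]]:
        return sorted(self.af.items(), key=lambda kv: (-kv[1], kv[0]))

    def __len__(self) -> int:
        return len(self.af)


def default_donors(traj: Trajectory) -> Selection:
    """Backbone N, template sidechain donors, and generator pseudo-donors."""
    idx = [
        i
        for i, a in enumerate(traj.topology)
        if a.name == "N"
        or a.name == PSEUDO_DONOR
        or a.name in SIDECHAIN_DONORS.get(a.res_name, ())
    ]
    return Selection(indices=tuple(idx), expression="default donors")


def default_acceptors(traj: Trajectory) -> Selection:
    idx = [
        i
        for i, a in enumerate(traj.topology)
        if a.name == "O"
        or a.name == PSEUDO_ACCEPTOR
        or a.name in SIDECHAIN_ACCEPTORS.get(a.res_name, ())
    ]
    return Selection(indices=tuple(idx), expression="default acceptors")


def _donor_hydrogens(
    traj: Trajectory, coords: np.ndarray, donors: Selection
) -> dict[int, list[np.ndarray]]:
    """Positions of hydrogens attached to each donor heavy atom.

    Explicit hydrogens within 1.25 A in the same residue are used when
    present; backbone amide hydrogens are otherwise rebuilt from
    heavy-atom geometry.
    """
    explicit: dict[int, list[np.ndarray]] = {}
    by_residue: dict[tuple[str, int], list[int]] = {}
    for i, atom in enumerate(traj.topology):
        if atom.element == "H":
            by_residue.setdefault((atom.chain_id, atom.res_seq), []).append(i)

    rebuilt: dict[int, np.ndarray] = {}
    needs_backbone_h = any(
        traj.topology[i].name == "N" for i in donors.indices
    )
    if needs_backbone_h:
        try:
            placed = place_amide_hydrogens(coords, traj.topology)
        except ValueError:
            placed = {}
        from .secstruct import backbone_indices

        residues = backbone_indices(traj.topology)
        for res_i, hpos in placed.items():
            rebuilt[residues[res_i]["N"]] = hpos

    for d in donors.indices:
        atom = traj.topology[d]
        hs = []
        for h in by_residue.get((atom.chain_id, atom.res_seq), []):
            if np.linalg.norm(coords[h] - coords[d]) <= 1.25:
                hs.append(coords[h])
        if not hs and d in rebuilt:
            hs.append(rebuilt[d])
        if hs:
            explicit[d] = hs
    return explicit


def detect_hbonds(
    traj: Trajectory,
    frame_index: int,
    donors: Selection,
    acceptors: Selection,
    d_cut: float = DEFAULT_DISTANCE_CUTOFF,
    a_cut: float = DEFAULT_ANGLE_CUTOFF,
    backbone_exclusion: bool = True,
) -> list[HBondObservation]:
    """All (D, H, A) triples passing the distance and angle cutoffs.

    Same-residue pairs are always excluded; with ``backbone_exclusion``
    the trivially close backbone N(i)-O(i +/- 1) pairs are dropped too.
    """
    if len(donors) == 0 or len(acceptors) == 0:
        raise ValueError("empty donor or acceptor selection")
    if d_cut <= 0 or a_cut <= 0:
        raise ValueError("cutoffs must be positive")
    coords = traj.coords[frame_index]
    hydrogens = _donor_hydrogens(traj, coords, donors)

    acc_idx = acceptors.as_array()
    tree = cKDTree(coords[acc_idx])
    observations: list[HBondObservation] = []
    for d in donors.indices:
        if d not in hydrogens:
            continue
        datom = traj.topology[d]
        for k in tree.query_ball_point(coords[d], d_cut):
            a = int(acc_idx[k])
            aatom = traj.topology[a]
            if aatom.chain_id == datom.chain_id and aatom.res_seq == datom.res_seq:
                continue
            if (
                backbone_exclusion
                and datom.name == "N"
                and aatom.name == "O"
                and aatom.chain_id == datom.chain_id
                and abs(aatom.res_seq - datom.res_seq) <= 1
            ):
                continue
            dist = float(np.linalg.norm(coords[a] - coords[d]))
            for hpos in hydrogens[d]:
                v1 = coords[d] - hpos
                v2 = coords[a] - hpos
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle >= a_cut:
                    observations.append(
                        HBondObservation(
                            frame_index=frame_index,
                            donor_res=datom.res_seq,
                            donor_atom=datom.name,
                            acceptor_res=aatom.res_seq,
                            acceptor_atom=aatom.name,
                            distance=dist,
                            angle=angle,
                        )
                    )
                    break
    return observations


def frequencies(
    traj: Trajectory,
    region: tuple[int, int] = (16, 42),
    d_cut: float = DEFAULT_DISTANCE_CUTOFF,
    a_cut: float = DEFAULT_ANGLE_CUTOFF,
    donors: Selection | None = None,
    acceptors: Selection | None = None,
    backbone_exclusion: bool = True,
) -> HBondFrequencyTable:
    """Residue-pair H-bond frequency table restricted to a residue region.

    af(pair) = 100 * (#frames with at least one bond for the pair) /
    (#frames); both residues must lie in ``region`` (inclusive).
    """
    if traj.n_frames < 1:
        raise ValueError("zero frames")
    lo, hi = region
    if lo > hi:
        raise ValueError(f"invalid region {region}")
    donors = donors if donors is not None else default_donors(traj)
    acceptors = acceptors if acceptors is not None else default_acceptors(traj)

    counts: dict[tuple[int, int], int] = {}
    for f in range(traj.n_frames):
        obs = detect_hbonds(
            traj, f, donors, acceptors, d_cut=d_cut, a_cut=a_cut,
            backbone_exclusion=backbone_exclusion,
        )
        seen: set[tuple[int, int]] = set()
        for ob in obs:
            if not (lo <= ob.donor_res <= hi and lo <= ob.acceptor_res <= hi):
                continue
            pair = (min(ob.donor_res, ob.acceptor_res), max(ob.donor_res, ob.acceptor_res))
            seen.add(pair)
        for pair in seen:
            counts[pair] = counts.get(pair, 0) + 1

    af = {pair: 100.0 * c / traj.n_frames for pair, c in counts.items()}
    return HBondFrequencyTable(af=af)


def turn_contact_filter(
    table: HBondFrequencyTable, min_af: float = 10.0
) -> HBondFrequencyTable:
    """Keep pairs with af >= min_af, sorted by descending frequency."""
    kept = {pair: v for pair, v in table.af.items() if v >= min_af}
    ordered = dict(sorted(kept.items(), key=lambda kv: (-kv[1], kv[0])))
    return HBondFrequencyTable(af=ordered)
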