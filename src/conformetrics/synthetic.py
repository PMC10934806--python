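"""Synthetic conformer and fibril generators with machine-readable ground truth.

Everything downstream is tested against structures built here: ideal
helices and strands from internal coordinates (NeRF chain extension),
U-shaped hairpins assembled from two antiparallel helical arms, coil
frames from random dihedrals, and S-shaped fibril stacks with a fixed
inter-strand rise, a programmable fan-opening hinge, and programmable
strand dissociation.  Atoms are backbone N/CA/C/O plus a CB placeholder
(sidechain realism is out of scope); scripted hydrogen-bond contacts
are realised with pseudo donor/acceptor probe atoms placed at exact
geometries, which are exempt from coordinate noise so that scheduled
contact frequencies are recovered exactly.

Fixed seed implies bit-identical output; different seeds change only
the noise, never the programmed schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .structio import AtomRecord, ATOMIC_MASSES, Trajectory

__all__ = [
    "AB42_SEQUENCE",
    "DihedralSchedule",
    "ContactScript",
    "MonomerEnsembleSpec",
    "DissociationEvent",
    "FibrilSpec",
    "mutate",
    "build_backbone",
    "helix_frame",
    "extended_frame",
    "coil_frame",
    "hairpin_frame",
    "make_monomer_ensemble",
    "make_antiparallel_sheet",
    "fibril_ca_template",
    "make_fibril",
]

#: 42-residue amyloid-beta peptide, author numbering Asp1..Ala42.
AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Backbone internal coordinates (Angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.5

_CONTACT_ON_DISTANCE = 2.9
_CONTACT_OFF_DISTANCE = 8.0


def mutate(sequence: str, mutation: str) -> str:
    """Apply a point mutation such as ``E22K`` (1-based position)."""
    wt, pos, new = mutation[0], int(mutation[1:-1]), mutation[-1]
    if not 1 <= pos <= len(sequence):
        raise ValueError(f"mutation position {pos} outside sequence")
    if sequence[pos - 1] != wt:
        raise ValueError(
            f"mutation {mutation}: position {pos} is {sequence[pos - 1]}, not {wt}"
        )
    if new not in ONE_TO_THREE:
        raise ValueError(f"unknown residue code {new!r}")
    return sequence[: pos - 1] + new + sequence[pos:]


@dataclass(frozen=True)
class DihedralSchedule:
    """Per-residue (phi, psi, omega) in degrees."""

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray

    @classmethod
    def uniform(cls, n: int, phi: float, psi: float, omega: float = 180.0):
        return cls(
            phi=np.full(n, float(phi)),
            psi=np.full(n, float(psi)),
            omega=np.full(n, float(omega)),
        )

    @classmethod
    def alpha(cls, n: int) -> "DihedralSchedule":
        return cls.uniform(n, -57.0, -47.0)

    @classmethod
    def beta(cls, n: int) -> "DihedralSchedule":
        return cls.uniform(n, -135.0, 135.0)

    def __len__(self) -> int:
        return len(self.phi)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """NeRF placement: new atom bonded to c, angle at c vs b, torsion a-b-c-new."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.cos(chi) * np.sin(theta),
            bond * np.sin(chi) * np.sin(theta),
        ]
    )
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def _residue_atom_names(code: str) -> list[str]:
    names = ["N", "CA", "C", "O"]
    if code != "G":
        names.append("CB")
    return names


def monomer_topology(
    sequence: str,
    start_res: int = 1,
    chain_id: str = "A",
    contact_residues: tuple[set[int], set[int]] | None = None,
) -> list[AtomRecord]:
    """Shared topology for all generated monomer frames.

    ``contact_residues`` adds pseudo donor atoms (ND + HD) and pseudo
    acceptor atoms (OA) to the listed author-numbered residues.
    """
    donors, acceptors = contact_residues or (set(), set())
    topo: list[AtomRecord] = []
    serial = 0
    for i, code in enumerate(sequence):
        res_seq = start_res + i
        names = list(_residue_atom_names(code))
        if res_seq in donors:
            names += ["ND", "HD"]
        if res_seq in acceptors:
            names += ["OA"]
        for name in names:
            serial += 1
            element = {"ND": "N", "HD": "H", "OA": "O"}.get(name, name[0])
            topo.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    res_name=ONE_TO_THREE[code],
                    chain_id=chain_id,
                    res_seq=res_seq,
                    element=element,
                    mass=ATOMIC_MASSES[element],
                )
            )
    return topo


def build_backbone(
    sequence: str, schedule: DihedralSchedule
) -> dict[str, np.ndarray]:
    """Backbone coordinates from internal-coordinate chain extension.

    Returns per-atom-name arrays keyed 'N', 'CA', 'C', 'O', 'CB'
    (CB rows are NaN for glycine); deterministic for fixed inputs.
    """
    n_res = len(sequence)
    if len(schedule) != n_res:
        raise ValueError("schedule length must match sequence length")
    for code in sequence:
        if code not in ONE_TO_THREE:
            raise ValueError(f"unknown residue code {code!r}")

    N = np.empty((n_res, 3))
    CA = np.empty((n_res, 3))
    C = np.empty((n_res, 3))
    O = np.empty((n_res, 3))
    CB = np.full((n_res, 3), np.nan)

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(n_res):
        if i > 0:
            N[i] = _place(
                N[i - 1], CA[i - 1], C[i - 1],
                BOND_C_N, ANGLE_CA_C_N, schedule.psi[i - 1],
            )
            CA[i] = _place(
                CA[i - 1], C[i - 1], N[i],
                BOND_N_CA, ANGLE_C_N_CA, schedule.omega[i - 1],
            )
            C[i] = _place(
                C[i - 1], N[i], CA[i],
                BOND_CA_C, ANGLE_N_CA_C, schedule.phi[i],
            )
        O[i] = _place(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, schedule.psi[i] - 180.0)
        if sequence[i] != "G":
            CB[i] = _place(C[i], N[i], CA[i], BOND_CA_CB, ANGLE_N_CA_CB, -122.6)

    return {"N": N, "CA": CA, "C": C, "O": O, "CB": CB}


def _assemble(sequence: str, atoms: dict[str, np.ndarray]) -> np.ndarray:
    """Flatten per-name arrays into topology atom order (no pseudo atoms)."""
    rows = []
    for i, code in enumerate(sequence):
        for name in _residue_atom_names(code):
            rows.append(atoms[name][i])
    return np.array(rows)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a to unit vector b (Rodrigues)."""
    a, b = _unit(a), _unit(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # Antiparallel: rotate 180 deg about any perpendicular axis.
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = _unit(np.cross(a, perp))
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _align_helix(atoms: dict[str, np.ndarray], direction: np.ndarray) -> dict:
    """Rotate a built segment so its CA best-fit axis points along ``direction``
    and its first CA sits at the origin."""
    ca = atoms["CA"]
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    rot = _rotation_between(axis, np.asarray(direction, dtype=float))
    out = {}
    origin = ca[0]
    for name, arr in atoms.items():
        out[name] = (arr - origin) @ rot.T
    return out


def helix_frame(sequence: str = AB42_SEQUENCE) -> np.ndarray:
    return _assemble(sequence, build_backbone(sequence, DihedralSchedule.alpha(len(sequence))))


def extended_frame(sequence: str = AB42_SEQUENCE) -> np.ndarray:
    return _assemble(sequence, build_backbone(sequence, DihedralSchedule.beta(len(sequence))))


def coil_frame(sequence: str, rng: np.random.Generator) -> np.ndarray:
    """Noise-dominated conformer from uniformly random phi/psi."""
    n = len(sequence)
    schedule = DihedralSchedule(
        phi=rng.uniform(-180.0, 180.0, n),
        psi=rng.uniform(-180.0, 180.0, n),
        omega=np.full(n, 180.0),
    )
    return _assemble(sequence, build_backbone(sequence, schedule))


def _pseudo_backbone_from_trace(
    ca: np.ndarray, perp: np.ndarray
) -> dict[str, np.ndarray]:
    """Approximate N/C/O/CB placement around an arbitrary CA trace.

    Adequate for turn linkers and fibril templates whose analyses are
    CA-based; not meant to satisfy helix/sheet hydrogen-bond geometry.
    """
    n = len(ca)
    tang = np.empty_like(ca)
    tang[0] = ca[1] - ca[0]
    tang[-1] = ca[-1] - ca[-2]
    tang[1:-1] = ca[2:] - ca[:-2]
    tang = tang / np.linalg.norm(tang, axis=1)[:, None]
    perp = _unit(np.asarray(perp, dtype=float))
    side = np.cross(tang, perp)
    side = side / np.maximum(np.linalg.norm(side, axis=1)[:, None], 1e-9)
    return {
        "N": ca - BOND_N_CA * tang,
        "CA": ca.copy(),
        "C": ca + BOND_CA_C * tang,
        "O": ca + BOND_CA_C * tang + BOND_C_O * perp,
        "CB": ca + BOND_CA_CB * side,
    }


def hairpin_frame(
    sequence: str = AB42_SEQUENCE,
    arm_break: tuple[int, int] = (21, 28),
    separation: float = 9.0,
) -> np.ndarray:
    """U-shaped hairpin: two antiparallel helical arms plus an arc turn.

    Residues 1..arm_break[0] form a helix along +x, residues
    arm_break[1]..n an antiparallel helix offset by ``separation`` in y,
    and the residues between them follow a circular-arc linker, closing
    the turn so the arms face each other within ~10 A.
    """
    n = len(sequence)
    stop1, start2 = arm_break
    seq1, seq2 = sequence[:stop1], sequence[start2 - 1 :]
    arm1 = _align_helix(
        build_backbone(seq1, DihedralSchedule.alpha(len(seq1))), np.array([1.0, 0, 0])
    )
    arm2 = _align_helix(
        build_backbone(seq2, DihedralSchedule.alpha(len(seq2))), np.array([-1.0, 0, 0])
    )
    # Place the start of arm 2 above the end of arm 1.
    ca1_end = arm1["CA"][-1]
    offset = ca1_end + np.array([1.5, separation, 0.0]) - arm2["CA"][0]
    arm2 = {name: arr + offset for name, arr in arm2.items()}

    # Turn linker CAs on a quadratic Bezier bulging outward in +x.
    n_turn = start2 - stop1 - 1
    p0, p2 = arm1["CA"][-1], arm2["CA"][0]
    p1 = 0.5 * (p0 + p2) + np.array([6.0, 0.0, 0.0])
    t = np.linspace(0.0, 1.0, n_turn + 2)[1:-1][:, None]
    trace = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    turn = _pseudo_backbone_from_trace(
        np.vstack([p0, trace, p2]), np.array([0.0, 0.0, 1.0])
    )
    turn = {name: arr[1:-1] for name, arr in turn.items()}

    merged = {
        name: np.vstack([arm1[name], turn[name], arm2[name]])
        for name in ("N", "CA", "C", "O", "CB")
    }
    return _assemble(sequence, merged)


@dataclass(frozen=True)
class ContactScript:
    """Scripted residue-pair hydrogen-bond schedule.

    The donor residue carries pseudo atoms ND/HD, the acceptor residue
    OA.  In 'on' frames the probe triplet is collinear with
    d(ND, OA) = 2.9 A; in 'off' frames the acceptor is parked 8 A away.
    ``fraction`` selects the first round(fraction * n_frames) frames;
    ``frames`` gives an explicit frame set instead.
    """

    donor_res: int
    acceptor_res: int
    fraction: float | None = None
    frames: tuple[int, ...] | None = None

    def on_frames(self, n_frames: int) -> set[int]:
        if self.frames is not None:
            return {f for f in self.frames if 0 <= f < n_frames}
        if self.fraction is None:
            raise ValueError("contact script needs a fraction or explicit frames")
        return set(range(int(round(self.fraction * n_frames))))


@dataclass
class MonomerEnsembleSpec:
    """Mixture ensemble of monomer conformer classes."""

    sequence: str = AB42_SEQUENCE
    weights: dict[str, float] = field(default_factory=lambda: {"u": 1.0})
    noise: float = 0.0
    n_frames: int = 1
    seed: int = 0
    contacts: list[ContactScript] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        known = {"helix", "u", "extended", "coil"}
        if not self.weights or any(k not in known for k in self.weights):
            raise ValueError(f"weights must be over {sorted(known)}")
        if any(w < 0 for w in self.weights.values()) or sum(self.weights.values()) <= 0:
            raise ValueError("weights must be non-negative with positive sum")


def _class_counts(weights: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment: counts sum to n exactly."""
    total = sum(weights.values())
    shares = {k: n * w / total for k, w in weights.items()}
    counts = {k: int(np.floor(s)) for k, s in shares.items()}
    short = n - sum(counts.values())
    leftovers = sorted(
        shares, key=lambda k: (-(shares[k] - counts[k]), k)
    )
    for k in leftovers[:short]:
        counts[k] += 1
    return counts


def make_monomer_ensemble(
    spec: MonomerEnsembleSpec,
) -> tuple[Trajectory, pd.DataFrame]:
    """Generate the ensemble and its ground-truth log.

    Class counts are deterministic (largest remainder on the weights);
    the seed controls only the frame order shuffle, the coil dihedrals,
    and the Gaussian coordinate noise.  The log has one row per frame
    with the class label and scripted-contact flags.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec.weights, spec.n_frames)
    labels = [k for k in sorted(counts) for _ in range(counts[k])]
    rng.shuffle(labels)

    donors = {c.donor_res for c in spec.contacts}
    acceptors = {c.acceptor_res for c in spec.contacts}
    topo = monomer_topology(
        spec.sequence,
        contact_residues=(donors, acceptors) if spec.contacts else None,
    )
    n_atoms = len(topo)
    atom_pos = {  # (res_seq, name) -> topology index
        (a.res_seq, a.name): i for i, a in enumerate(topo)
    }

    base: dict[str, np.ndarray] = {}
    coords = np.empty((spec.n_frames, n_atoms, 3))
    on_sets = [c.on_frames(spec.n_frames) for c in spec.contacts]

    for f, label in enumerate(labels):
        if label == "coil":
            frame = coil_frame(spec.sequence, rng)
        else:
            if label not in base:
                builder = {
                    "helix": helix_frame,
                    "extended": extended_frame,
                    "u": hairpin_frame,
                }[label]
                base[label] = builder(spec.sequence)
            frame = base[label].copy()
        if spec.noise > 0:
            frame = frame + rng.normal(0.0, spec.noise, frame.shape)

        full = np.zeros((n_atoms, 3))
        k = 0
        for i, atom in enumerate(topo):
            if atom.name in ("ND", "HD", "OA"):
                continue
            full[i] = frame[k]
            k += 1
        # Scripted probes: exact placement, exempt from noise.
        for script, on in zip(spec.contacts, on_sets):
            cb_d = full[atom_pos[(script.donor_res, "CB")]]
            cb_a = full[atom_pos[(script.acceptor_res, "CB")]]
            u = _unit(cb_a - cb_d) if np.linalg.norm(cb_a - cb_d) > 1e-6 else np.array([1.0, 0, 0])
            nd = cb_d + 1.0 * u
            hd = nd + 1.0 * u
            dist = _CONTACT_ON_DISTANCE if f in on else _CONTACT_OFF_DISTANCE
            oa = nd + dist * u
            full[atom_pos[(script.donor_res, "ND")]] = nd
            full[atom_pos[(script.donor_res, "HD")]] = hd
            full[atom_pos[(script.acceptor_res, "OA")]] = oa
        coords[f] = full

    log = pd.DataFrame({"frame": np.arange(spec.n_frames), "label": labels})
    for script, on in zip(spec.contacts, on_sets):
        col = f"contact_{script.donor_res}_{script.acceptor_res}"
        log[col] = [int(f in on) for f in range(spec.n_frames)]

    traj = Trajectory(topology=topo, coords=coords)
    traj.validate()
    return traj, log


# ---------------------------------------------------------------------------
# Antiparallel two-strand sheet (reference fixture for sheet assignment)
# ---------------------------------------------------------------------------

def _ks_pair_energy_arrays(
    c1: np.ndarray, o1: np.ndarray, n2: np.ndarray, h2: np.ndarray
) -> np.ndarray:
    """Vectorised Kabsch-Sander energies for acceptor x donor arrays."""
    def dists(a, b):
        return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)

    r_on = dists(o1, n2)
    r_ch = dists(c1, h2)
    r_oh = dists(o1, h2)
    r_cn = dists(c1, n2)
    with np.errstate(divide="ignore"):
        e = 27.888 * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    e[np.minimum(np.minimum(r_on, r_ch), np.minimum(r_oh, r_cn)) < 0.5] = np.inf
    return e


def _strand_hn(atoms: dict[str, np.ndarray]) -> np.ndarray:
    """Amide H positions for a built strand (no H for the first residue)."""
    n = atoms["N"]
    h = np.full_like(n, np.nan)
    for i in range(1, len(n)):
        u1 = _unit(atoms["C"][i - 1] - n[i])
        u2 = _unit(atoms["CA"][i] - n[i])
        h[i] = n[i] - _unit(u1 + u2)
    return h


def make_antiparallel_sheet(
    sequence: str = "VTVKVTVK", separation_guess: float = 4.8
) -> tuple[list[AtomRecord], np.ndarray]:
    """Two antiparallel beta strands with optimised inter-strand H-bonding.

    Strand 1 is an ideal extended strand; strand 2 is its 180-degree
    rotation (chain direction reversed), rigidly translated to minimise
    the total inter-strand Kabsch-Sander energy.  Deterministic.
    """
    atoms1 = _align_helix(
        build_backbone(sequence, DihedralSchedule.beta(len(sequence))),
        np.array([1.0, 0.0, 0.0]),
    )
    h1 = _strand_hn(atoms1)

    def rotated(Rmat):
        return {name: arr @ Rmat.T for name, arr in atoms1.items()}

    rot_y = np.diag([-1.0, 1.0, -1.0])
    rot_z = np.diag([-1.0, -1.0, 1.0])

    def energy(shift: np.ndarray, atoms2: dict[str, np.ndarray]) -> float:
        a2 = {name: arr + shift for name, arr in atoms2.items()}
        h2 = _strand_hn(a2)
        e12 = _ks_pair_energy_arrays(atoms1["C"], atoms1["O"], a2["N"][1:], h2[1:])
        e21 = _ks_pair_energy_arrays(a2["C"], a2["O"], atoms1["N"][1:], h1[1:])
        total = 0.0
        for e in (e12, e21):
            bonded = e[np.isfinite(e) & (e < -0.5)]
            total += float(bonded.sum())
        # Penalise steric overlap of CA traces.
        dca = np.linalg.norm(
            atoms1["CA"][:, None, :] - a2["CA"][None, :, :], axis=2
        )
        total += 10.0 * float(np.clip(3.8 - dca, 0.0, None).sum())
        return total

    mid = atoms1["CA"].mean(axis=0)
    best: tuple[float, dict] | None = None
    for Rmat in (rot_y, rot_z):
        atoms2 = rotated(Rmat)
        recenter = mid - atoms2["CA"].mean(axis=0)
        for dy in (separation_guess, -separation_guess):
            for dx in (-1.7, 0.0, 1.7):
                start = recenter + np.array([dx, dy, 0.0])
                res = minimize(
                    lambda s, a2=atoms2: energy(s, a2),
                    start,
                    method="Nelder-Mead",
                    options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
                )
                if best is None or res.fun < best[0]:
                    best = (float(res.fun), {n: a + res.x for n, a in atoms2.items()})

    assert best is not None
    atoms2 = best[1]

    topo = monomer_topology(sequence, start_res=1, chain_id="A") + monomer_topology(
        sequence, start_res=len(sequence) + 3, chain_id="B"
    )
    coords = np.vstack([_assemble(sequence, atoms1), _assemble(sequence, atoms2)])
    return topo, coords


# ---------------------------------------------------------------------------
# S-shaped fibril stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DissociationEvent:
    """Axial displacement opening a gap in the stack.

    From ``from_frame`` on, strand ``strand`` is shifted by ``offset``
    along the stacking axis; with ``shift_above`` every higher strand
    moves too, so exactly one interstrand gap opens.
    """

    strand: int  # 1-based strand index along the stacking axis
    offset: float  # Angstrom
    from_frame: int = 0
    shift_above: bool = True


@dataclass
class FibrilSpec:
    """S-shaped stack with programmable fan opening and dissociation."""

    sequence: str = AB42_SEQUENCE
    n_strands: int = 10
    rise: float = 4.8  # canonical cross-beta stacking distance
    n_frames: int = 1
    start_res: int = 1
    noise: float = 0.0
    seed: int = 0
    dve_targets: np.ndarray | None = None  # per-frame Glu11-Val39 targets
    dissociation: list[DissociationEvent] = field(default_factory=list)
    hinge_residue: int = 28
    hinge_last_moving: int = 21

    def validate(self) -> None:
        if self.n_strands < 2:
            raise ValueError("n_strands must be >= 2")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.dve_targets is not None and len(self.dve_targets) != self.n_frames:
            raise ValueError("dve_targets must have one value per frame")
        if self.start_res not in (1, 11):
            raise ValueError("start_res must be 1 or 11")


def fibril_ca_template(start_res: int = 1) -> dict[int, np.ndarray]:
    """In-plane CA trace of one S-shaped strand, keyed by author residue.

    Three rows linked by two turns: residues <=21 along +x at y=0
    (the N-terminal tail extends the first row), 24-34 along -x at
    y=5, 37-42 along +x at y=10; turn residues bridge the rows.
    """
    pos: dict[int, np.ndarray] = {}
    for i in range(start_res, 22):
        pos[i] = np.array([(i - 11) * 3.8, 0.0, 0.0])
    pos[22] = np.array([41.0, 1.0, 0.0])
    pos[23] = np.array([41.0, 4.0, 0.0])
    for i in range(24, 35):
        pos[i] = np.array([(34 - i) * 3.8, 5.0, 0.0])
    pos[35] = np.array([-3.0, 6.0, 0.0])
    pos[36] = np.array([-3.0, 9.0, 0.0])
    for i in range(37, 43):
        pos[i] = np.array([(i - 37) * 3.8, 10.0, 0.0])
    return pos


def _hinge_angle_for_target(
    template: dict[int, np.ndarray], target: float,
    hinge_residue: int, ve_pair: tuple[int, int] = (11, 39),
) -> float:
    """Signed in-plane hinge rotation (radians) achieving a D_VE target."""
    p = template[hinge_residue][:2]
    v = template[ve_pair[0]][:2] - p
    a = template[ve_pair[1]][:2] - p
    la, lv = np.linalg.norm(a), np.linalg.norm(v)
    cos_alpha = (la**2 + lv**2 - target**2) / (2 * la * lv)
    if not -1.0 <= cos_alpha <= 1.0:
        raise ValueError(
            f"D_VE target {target:.2f} A outside reachable range "
            f"[{abs(la - lv):.2f}, {la + lv:.2f}]"
        )
    alpha = np.arccos(cos_alpha)
    phi_v = np.arctan2(a[0] * v[1] - a[1] * v[0], float(np.dot(a, v)))
    sign = 1.0 if phi_v >= 0 else -1.0
    return sign * alpha - phi_v


def _strand_chain_ids(n: int) -> list[str]:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"
    if n > len(alphabet):
        raise ValueError(f"cannot label more than {len(alphabet)} strands")
    return list(alphabet[:n])


def make_fibril(spec: FibrilSpec) -> tuple[Trajectory, pd.DataFrame]:
    """Generate an S-shaped stack trajectory plus its ground-truth log.

    The strand template is replicated along +z at the given rise; the
    fan schedule rotates each strand's N-terminal half (residues up to
    ``hinge_last_moving``) about the vertical axis through its hinge
    residue, with the per-frame angle solved so the noise-free
    Glu11-Val39 distance equals the target; dissociation offsets are
    applied along z; Gaussian noise is added last.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    template = fibril_ca_template(spec.start_res)
    res_ids = sorted(template)
    seq = spec.sequence[spec.start_res - 1 :]
    if len(seq) != len(res_ids):
        raise ValueError("sequence length inconsistent with start_res")

    ca = np.array([template[i] for i in res_ids])
    atoms = _pseudo_backbone_from_trace(ca, np.array([0.0, 0.0, 1.0]))
    moving = np.array([i <= spec.hinge_last_moving for i in res_ids])
    pivot = template[spec.hinge_residue]

    chain_ids = _strand_chain_ids(spec.n_strands)
    topo: list[AtomRecord] = []
    for cid in chain_ids:
        topo.extend(monomer_topology(seq, start_res=spec.start_res, chain_id=cid))

    # Template atom rows in topology order for one strand.
    strand_template = np.array(
        [
            atoms[name][r]
            for r, code in enumerate(seq)
            for name in _residue_atom_names(code)
        ]
    )
    atom_moving = np.array(
        [
            moving[r]
            for r, code in enumerate(seq)
            for _ in _residue_atom_names(code)
        ]
    )

    # Per-frame, per-strand axial offsets from dissociation events.
    offsets = np.zeros((spec.n_frames, spec.n_strands))
    for ev in spec.dissociation:
        if not 1 <= ev.strand <= spec.n_strands:
            raise ValueError(f"dissociation strand {ev.strand} out of range")
        lo = ev.strand - 1
        hi = spec.n_strands if ev.shift_above else ev.strand
        offsets[ev.from_frame :, lo:hi] += ev.offset

    angles = np.zeros(spec.n_frames)
    if spec.dve_targets is not None:
        for f, target in enumerate(np.asarray(spec.dve_targets, dtype=float)):
            angles[f] = _hinge_angle_for_target(
                template, target, spec.hinge_residue
            )

    n_strand_atoms = strand_template.shape[0]
    coords = np.empty((spec.n_frames, spec.n_strands * n_strand_atoms, 3))
    for f in range(spec.n_frames):
        frame_strand = strand_template.copy()
        if angles[f] != 0.0:
            ct, st = np.cos(angles[f]), np.sin(angles[f])
            rel = frame_strand[atom_moving] - pivot
            rotated = rel.copy()
            rotated[:, 0] = ct * rel[:, 0] - st * rel[:, 1]
            rotated[:, 1] = st * rel[:, 0] + ct * rel[:, 1]
            frame_strand[atom_moving] = rotated + pivot
        for s in range(spec.n_strands):
            block = frame_strand.copy()
            block[:, 2] += s * spec.rise + offsets[f, s]
            coords[f, s * n_strand_atoms : (s + 1) * n_strand_atoms] = block
        if spec.noise > 0:
            coords[f] += rng.normal(0.0, spec.noise, coords[f].shape)

    log = pd.DataFrame({"frame": np.arange(spec.n_frames)})
    if spec.dve_targets is not None:
        log["dve_target"] = np.asarray(spec.dve_targets, dtype=float)
    for s in range(spec.n_strands):
        log[f"offset_strand_{s + 1}"] = offsets[:, s]

    traj = Trajectory(topology=topo, coords=coords)
    traj.validate()
    return traj, log
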