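"""Multi-model PDB I/O and residue/atom selections.

Structures are held as a :class:`Trajectory`: an ordered atom topology
shared by every frame plus an ``(n_frames, n_atoms, 3)`` coordinate
array.  Residue numbering is the author numbering of the input file
(1-based, e.g. Asp1...Ala42 for the 42-residue amyloid-beta peptide;
fibril chains built on a 2MXU-like template may start at residue 11).
The reader never renumbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "Selection",
    "PDBFormatError",
    "read_pdb_models",
    "write_pdb_models",
    "select",
]

#: Standard atomic masses (amu) for the elements that occur in peptides.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

#: Residue names stripped on read when ``strip_solvent`` is set.
SOLVENT_RESNAMES = frozenset(
    {"HOH", "WAT", "TIP3", "SOL", "NA", "CL", "K", "MG", "ZN", "CA2", "NA+", "CL-"}
)


class PDBFormatError(ValueError):
    """Raised for unparseable or inconsistent PDB content."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology."""

    serial: int
    name: str
    res_name: str
    chain_id: str
    res_seq: int
    element: str
    mass: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial} {self.name}: mass must be > 0")


@dataclass(frozen=True)
class Frame:
    """Coordinates of one conformation, in Angstrom."""

    coords: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("frame coordinates must have shape (n_atoms, 3)")
        if not np.isfinite(coords).all():
            raise ValueError("frame contains non-finite coordinates")
        object.__setattr__(self, "coords", coords)


@dataclass
class Trajectory:
    """Ordered conformations sharing one atom topology."""

    topology: list[AtomRecord]
    coords: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.coords.shape[1] != len(self.topology):
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology atom count {len(self.topology)}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def chain_ids(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for atom in self.topology:
            seen.setdefault(atom.chain_id, None)
        return list(seen)

    def frame(self, i: int) -> Frame:
        return Frame(self.coords[i], frame_index=i)

    def frames(self) -> Iterable[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def masses(self, indices: Sequence[int] | None = None) -> np.ndarray:
        atoms = self.topology if indices is None else [self.topology[i] for i in indices]
        return np.array([a.mass for a in atoms], dtype=float)

    def residue_range(self, chain_id: str) -> tuple[int, int]:
        seqs = [a.res_seq for a in self.topology if a.chain_id == chain_id]
        if not seqs:
            raise KeyError(f"no such chain: {chain_id!r}")
        return min(seqs), max(seqs)


@dataclass(frozen=True)
class Selection:
    """Sorted, unique 0-based atom indices into a topology."""

    indices: tuple[int, ...]
    expression: str = ""

    def __post_init__(self) -> None:
        idx = tuple(self.indices)
        if list(idx) != sorted(set(idx)):
            raise ValueError("selection indices must be unique and sorted")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.array(self.indices, dtype=int)


def infer_element(name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Digits are stripped; a leading H in hydrogen names such as ``1HB``
    or ``HD21`` resolves to hydrogen; otherwise the first letter wins.
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise PDBFormatError(f"cannot infer element from atom name {name!r}")
    return stripped[0].upper()


def _mass_for(element: str) -> float:
    try:
        return ATOMIC_MASSES[element]
    except KeyError:
        raise PDBFormatError(f"no mass tabulated for element {element!r}") from None


def _parse_atom_line(line: str, lineno: int) -> dict:
    # PDB v3.3 fixed columns.
    try:
        return {
            "serial": int(line[6:11]),
            "name": line[12:16].strip(),
            "altloc": line[16].strip(),
            "res_name": line[17:20].strip(),
            "chain_id": line[21].strip() or "A",
            "res_seq": int(line[22:26]),
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
            "occupancy": float(line[54:60]) if line[54:60].strip() else 1.0,
            "element": line[76:78].strip() if len(line) >= 78 else "",
        }
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"unparseable ATOM record at line {lineno}: {exc}") from None


def _resolve_altlocs(atoms: list[dict]) -> list[dict]:
    """Keep one atom per (chain, res_seq, name): highest occupancy, tie -> 'A'/blank."""
    best: dict[tuple, dict] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (atom["chain_id"], atom["res_seq"], atom["name"])
        rank = (-atom["occupancy"], atom["altloc"])  # blank sorts before 'A' < 'B'
        if key not in best:
            best[key] = atom
            order.append(key)
        elif rank < (-best[key]["occupancy"], best[key]["altloc"]):
            best[key] = atom
    return [best[k] for k in order]


def read_pdb_models(path: str | Path, strip_solvent: bool = True) -> Trajectory:
    """Read a single- or multi-model PDB file into a :class:`Trajectory`.

    One frame per MODEL record; a file without MODEL records yields a
    single frame.  Alternate locations are resolved to the highest
    occupancy (ties prefer altloc 'A').  All models must present the
    same atoms in the same order.
    """
    path = Path(path)
    models: list[list[dict]] = []
    current: list[dict] = []
    in_model = False
    model_ids: list[int] = []

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                if in_model:
                    raise PDBFormatError(f"nested MODEL record at line {lineno}")
                in_model = True
                current = []
                try:
                    model_ids.append(int(line[6:].split()[0]))
                except (ValueError, IndexError):
                    model_ids.append(len(models) + 1)
            elif record == "ENDMDL":
                if not in_model:
                    raise PDBFormatError(f"ENDMDL without MODEL at line {lineno}")
                models.append(current)
                in_model = False
            elif record in ("ATOM", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                if strip_solvent and atom["res_name"] in SOLVENT_RESNAMES:
                    continue
                current.append(atom)

    if in_model:
        raise PDBFormatError("file ends inside an open MODEL block")
    if not models:
        if not current:
            raise PDBFormatError(f"{path}: no ATOM records found")
        models = [current]
        model_ids = [1]

    resolved = [_resolve_altlocs(m) for m in models]
    first = resolved[0]
    if not first:
        raise PDBFormatError(f"{path}: first model contains no atoms")
    signature = [(a["chain_id"], a["res_seq"], a["name"]) for a in first]
    for mid, model in zip(model_ids, resolved):
        sig = [(a["chain_id"], a["res_seq"], a["name"]) for a in model]
        if sig != signature:
            raise PDBFormatError(
                f"{path}: MODEL {mid} atom list differs from MODEL {model_ids[0]} "
                f"({len(sig)} vs {len(signature)} atoms)"
            )

    topology = []
    for atom in first:
        element = atom["element"] or infer_element(atom["name"])
        topology.append(
            AtomRecord(
                serial=atom["serial"],
                name=atom["name"],
                res_name=atom["res_name"],
                chain_id=atom["chain_id"],
                res_seq=atom["res_seq"],
                element=element,
                mass=_mass_for(element),
            )
        )

    coords = np.array(
        [[[a["x"], a["y"], a["z"]] for a in model] for model in resolved], dtype=float
    )
    traj = Trajectory(topology=topology, coords=coords)
    traj.validate()
    return traj


def _format_atom_name(name: str, element: str) -> str:
    # Single-letter elements with short names are right-padded from column 14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb_models(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as a multi-model PDB (one MODEL per frame).

    Round-trip guarantee: coordinates survive to 3 decimals and
    chain/residue numbering exactly.
    """
    traj.validate()
    if traj.n_atoms > 99999:
        raise ValueError("PDB format limit: more than 99999 atoms")
    path = Path(path)
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        prev_chain = None
        serial = 0
        for atom, xyz in zip(traj.topology, traj.coords[f]):
            if prev_chain is not None and atom.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = atom.chain_id
            serial += 1
            lines.append(
                "ATOM  {serial:5d} {name} {res:<3s} {chain}{seq:4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}".format(
                    serial=serial,
                    name=_format_atom_name(atom.name, atom.element),
                    res=atom.res_name,
                    chain=atom.chain_id,
                    seq=atom.res_seq,
                    x=xyz[0],
                    y=xyz[1],
                    z=xyz[2],
                    occ=1.00,
                    b=0.00,
                    elem=atom.element,
                )
            )
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def select(
    traj: Trajectory,
    chain: str | None = None,
    res_range: tuple[int, int] | None = None,
    atom_names: Iterable[str] | None = None,
    allow_empty: bool = False,
) -> Selection:
    """Select atoms by chain id, inclusive author-numbered residue range,
    and/or atom-name set.  Ordering follows the topology."""
    names = {n.strip() for n in atom_names} if atom_names is not None else None
    if res_range is not None:
        lo, hi = res_range
        if lo > hi:
            raise ValueError(f"invalid residue range {lo}-{hi}")
        chains = [chain] if chain is not None else traj.chain_ids
        covered = False
        for cid in chains:
            try:
                cmin, cmax = traj.residue_range(cid)
            except KeyError:
                raise ValueError(f"no such chain: {cid!r}") from None
            if lo >= cmin and hi <= cmax:
                covered = True
        if not covered:
            spans = ", ".join(
                f"{cid}:{traj.residue_range(cid)[0]}-{traj.residue_range(cid)[1]}"
                for cid in chains
            )
            raise ValueError(
                f"residue range {lo}-{hi} outside available ranges ({spans})"
            )

    indices = []
    for i, atom in enumerate(traj.topology):
        if chain is not None and atom.chain_id != chain:
            continue
        if res_range is not None and not (res_range[0] <= atom.res_seq <= res_range[1]):
            continue
        if names is not None and atom.name not in names:
            continue
        indices.append(i)
    if not indices and not allow_empty:
        raise ValueError(
            f"empty selection (chain={chain!r}, res_range={res_range}, atoms={names})"
        )
    expr = f"chain={chain} res={res_range} names={sorted(names) if names else None}"
    return Selection(indices=tuple(indices), expression=expr)
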