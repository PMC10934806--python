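"""Five-distance fibril compactness descriptors and fan-motion amplitude.

Strand order is inferred geometrically: the stacking axis is the
leading principal axis of the strand centroids and strands are numbered
1..n by their projection on it — never by chain-id alphabet.  Every
distance is measured between CA atoms:

==========  =====================================================
D_HC        CA(Gly33) of strand 3 <-> strand 8 (horizontal core)
D_VC        CA(Phe19)-CA(Val39) within each core strand, averaged
D_HE        CA(Gln15) of strand 3 <-> strand 8 (horizontal external)
D_VE        CA(Glu11)-CA(Val39) within each core strand, averaged
D_IS        adjacent core strands' CA(His14) pairs, plus their mean
==========  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import pca_modes
from .structio import Selection, Trajectory, select

__all__ = [
    "FibrilTopology",
    "DescriptorSeries",
    "ReferenceResidues",
    "infer_topology",
    "d_hc",
    "d_vc",
    "d_he",
    "d_ve",
    "d_is",
    "descriptor_series",
    "fan_amplitude",
]


@dataclass(frozen=True)
class ReferenceResidues:
    """Author-numbered residues anchoring each descriptor."""

    hc: int = 33  # Gly33
    vc: tuple[int, int] = (19, 39)  # Phe19 -> Val39
    he: int = 15  # Gln15
    ve: tuple[int, int] = (11, 39)  # Glu11 -> Val39
    is_: int = 14  # His14


@dataclass
class FibrilTopology:
    """Geometric strand ordering of a multi-chain stack."""

    strand_chains: list[str]  # chain ids ordered along the stacking axis
    strand_ranges: dict[str, tuple[int, int]]
    axis: np.ndarray  # unit stacking axis
    core_strands: list[int]  # 1-based strand indices
    reference: ReferenceResidues = field(default_factory=ReferenceResidues)

    @property
    def n_strands(self) -> int:
        return len(self.strand_chains)

    def chain_of(self, strand: int) -> str:
        """Chain id of a 1-based strand index."""
        if not 1 <= strand <= self.n_strands:
            raise ValueError(f"strand {strand} out of range 1-{self.n_strands}")
        return self.strand_chains[strand - 1]


@dataclass
class DescriptorSeries:
    """Per-frame values of the five descriptors plus summaries."""

    frames: np.ndarray
    hc: np.ndarray
    vc: np.ndarray
    he: np.ndarray
    ve: np.ndarray
    is_mean: np.ndarray
    is_pairs: dict[tuple[int, int], np.ndarray]  # (strand_i, strand_j) -> series

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for key, series in (
            ("D_HC", self.hc),
            ("D_VC", self.vc),
            ("D_HE", self.he),
            ("D_VE", self.ve),
            ("D_IS", self.is_mean),
        ):
            out[key] = {"mean": float(np.mean(series)), "sd": float(np.std(series))}
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {
            "frame": self.frames,
            "D_HC": self.hc,
            "D_VC": self.vc,
            "D_HE": self.he,
            "D_VE": self.ve,
            "D_IS_mean": self.is_mean,
        }
        for (i, j), series in sorted(self.is_pairs.items()):
            data[f"D_IS_{i}_{j}"] = series
        return pd.DataFrame(data)


def _strand_ca_centroids(traj: Trajectory, frame_index: int) -> dict[str, np.ndarray]:
    centroids = {}
    for cid in traj.chain_ids:
        sel = select(traj, chain=cid, atom_names={"CA"})
        centroids[cid] = traj.coords[frame_index, sel.as_array()].mean(axis=0)
    return centroids


def infer_topology(
    traj: Trajectory,
    core_margin: int = 2,
    reference: ReferenceResidues | None = None,
    frame_index: int = 0,
) -> FibrilTopology:
    """Order strands along the stacking axis and pick the core set.

    The stacking axis is the leading principal axis of the strand
    centroids (sign fixed so its largest-magnitude component is
    positive); the core excludes ``core_margin`` strands at each end.
    """
    chains = traj.chain_ids
    if len(chains) < 2:
        raise ValueError("fibril topology needs at least 2 chains")
    centroids = _strand_ca_centroids(traj, frame_index)
    pts = np.array([centroids[c] for c in chains])
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    peak = np.argmax(np.abs(axis))
    if axis[peak] < 0:
        axis = -axis

    proj = centered @ axis
    order = np.argsort(proj, kind="stable")
    sorted_proj = proj[order]
    gaps = np.diff(sorted_proj)
    if (gaps < 0.5).any():
        raise ValueError(
            "ambiguous strand ordering: two strand centroids project within 0.5 A"
        )
    ordered_chains = [chains[i] for i in order]
    n = len(ordered_chains)
    core = list(range(1 + core_margin, n - core_margin + 1))
    if not core:
        raise ValueError(f"core margin {core_margin} leaves no core strands")
    ranges = {c: traj.residue_range(c) for c in chains}
    return FibrilTopology(
        strand_chains=ordered_chains,
        strand_ranges=ranges,
        axis=axis,
        core_strands=core,
        reference=reference or ReferenceResidues(),
    )


def _ca(traj: Trajectory, frame_index: int, chain: str, res_seq: int) -> np.ndarray:
    sel = select(
        traj, chain=chain, res_range=(res_seq, res_seq), atom_names={"CA"},
        allow_empty=True,
    )
    if len(sel) != 1:
        raise ValueError(f"missing CA for residue {res_seq} in chain {chain!r}")
    return traj.coords[frame_index, sel.indices[0]]


def _cross_strand(
    traj: Trajectory, topo: FibrilTopology, frame_index: int,
    res_seq: int, strand_a: int, strand_b: int,
) -> float:
    pa = _ca(traj, frame_index, topo.chain_of(strand_a), res_seq)
    pb = _ca(traj, frame_index, topo.chain_of(strand_b), res_seq)
    return float(np.linalg.norm(pa - pb))


def _core_mean_intra(
    traj: Trajectory, topo: FibrilTopology, frame_index: int,
    res_pair: tuple[int, int],
) -> float:
    vals = []
    for strand in topo.core_strands:
        cid = topo.chain_of(strand)
        pa = _ca(traj, frame_index, cid, res_pair[0])
        pb = _ca(traj, frame_index, cid, res_pair[1])
        vals.append(np.linalg.norm(pa - pb))
    return float(np.mean(vals))


def d_hc(
    traj: Trajectory, topo: FibrilTopology, frame_index: int = 0,
    strands: tuple[int, int] = (3, 8),
) -> float:
    """Horizontal core distance: Gly33 CA of strand 3 vs strand 8."""
    return _cross_strand(traj, topo, frame_index, topo.reference.hc, *strands)


def d_he(
    traj: Trajectory, topo: FibrilTopology, frame_index: int = 0,
    strands: tuple[int, int] = (3, 8),
) -> float:
    """Horizontal external distance: Gln15 CA of strand 3 vs strand 8."""
    return _cross_strand(traj, topo, frame_index, topo.reference.he, *strands)


def d_vc(traj: Trajectory, topo: FibrilTopology, frame_index: int = 0) -> float:
    """Vertical core distance: mean Phe19-Val39 CA distance over core strands."""
    return _core_mean_intra(traj, topo, frame_index, topo.reference.vc)


def d_ve(traj: Trajectory, topo: FibrilTopology, frame_index: int = 0) -> float:
    """Vertical external distance: mean Glu11-Val39 CA distance over core strands."""
    return _core_mean_intra(traj, topo, frame_index, topo.reference.ve)


def d_is(
    traj: Trajectory, topo: FibrilTopology, frame_index: int = 0
) -> tuple[dict[tuple[int, int], float], float]:
    """Interstrand distances: adjacent core-strand His14 CA pairs + mean."""
    pairs: dict[tuple[int, int], float] = {}
    core = topo.core_strands
    for sa, sb in zip(core[:-1], core[1:]):
        pairs[(sa, sb)] = _cross_strand(
            traj, topo, frame_index, topo.reference.is_, sa, sb
        )
    if not pairs:
        raise ValueError("need at least two core strands for D_IS")
    return pairs, float(np.mean(list(pairs.values())))


def descriptor_series(traj: Trajectory, topo: FibrilTopology) -> DescriptorSeries:
    """All five descriptors evaluated on every frame."""
    n = traj.n_frames
    hc = np.empty(n)
    vc = np.empty(n)
    he = np.empty(n)
    ve = np.empty(n)
    is_mean = np.empty(n)
    pair_series: dict[tuple[int, int], np.ndarray] | None = None
    for f in range(n):
        hc[f] = d_hc(traj, topo, f)
        vc[f] = d_vc(traj, topo, f)
        he[f] = d_he(traj, topo, f)
        ve[f] = d_ve(traj, topo, f)
        pairs, is_mean[f] = d_is(traj, topo, f)
        if pair_series is None:
            pair_series = {p: np.empty(n) for p in pairs}
        for p, v in pairs.items():
            pair_series[p][f] = v
    return DescriptorSeries(
        frames=np.arange(n),
        hc=hc, vc=vc, he=he, ve=ve,
        is_mean=is_mean,
        is_pairs=pair_series or {},
    )


def fan_amplitude(
    traj: Trajectory,
    topo: FibrilTopology,
    series: DescriptorSeries | None = None,
) -> dict[str, float]:
    """Fan-motion amplitude (max - min of per-frame D_VE) and the
    variance fraction of the leading CA PCA mode."""
    if traj.n_frames < 10:
        raise ValueError("need at least 10 frames for fan-motion analysis")
    if series is None:
        series = descriptor_series(traj, topo)
    amplitude = float(series.ve.max() - series.ve.min())
    sel = select(traj, atom_names={"CA"})
    pca = pca_modes(traj, sel, n_modes=1)
    return {
        "amplitude": amplitude,
        "mode1_variance_fraction": float(pca.variance_fractions[0]),
    }
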