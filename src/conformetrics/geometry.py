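"""Rigid-body superposition, RMSD matrices, radius of gyration, and
coordinate PCA — the quantitative core shared by every analysis.

Conventions: superposition is SVD-based Kabsch with determinant
sign-correction (always a proper rotation); PCA operates on selected
atoms, mass-unweighted, after superposing every frame onto a reference
frame; each eigenmode's largest-magnitude component is made positive so
outputs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import Selection, Trajectory

__all__ = [
    "SuperpositionResult",
    "PCAResult",
    "GyrationSeries",
    "kabsch_superpose",
    "apply_superposition",
    "rmsd_all_to_all",
    "radius_of_gyration",
    "gyration_series",
    "pca_modes",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference.

    ``reference ~ mobile @ rotation.T + translation``
    """

    rotation: np.ndarray  # (3, 3), proper rotation
    translation: np.ndarray  # (3,)
    rmsd: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is a reflection")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


@dataclass(frozen=True)
class PCAResult:
    mean: np.ndarray  # (n_atoms, 3) mean of superposed coordinates
    modes: np.ndarray  # (n_modes, 3 * n_atoms), orthonormal rows
    variances: np.ndarray  # (n_modes,) descending, Angstrom^2
    projections: np.ndarray  # (n_frames, n_modes)
    total_variance: float

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.variances / self.total_variance


@dataclass(frozen=True)
class GyrationSeries:
    values: np.ndarray  # per-frame RoG, Angstrom

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation + translation minimising the (weighted)
    RMSD; reflections are excluded by the determinant sign-correction.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if mobile.ndim != 2 or mobile.shape[1] != 3 or n < 3:
        raise ValueError("need n >= 3 points of shape (n, 3)")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mob_c = mobile - w @ mobile
    ref_c = reference - w @ reference
    H = (mob_c * w[:, None]).T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = mob_c @ R.T - ref_c
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    t = (w @ reference) - R @ (w @ mobile)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def apply_superposition(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


def rmsd_all_to_all(
    traj: Trajectory,
    sel: Selection,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Symmetric matrix of pairwise best-fit RMSDs over selected atoms."""
    if len(sel) == 0:
        raise ValueError("empty selection")
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    coords = traj.coords[:, sel.as_array(), :]
    n = traj.n_frames
    matrix = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch_superpose(coords[j], coords[i], weights=weights).rmsd
            matrix[i, j] = matrix[j, i] = r
    return matrix


def radius_of_gyration(
    coords: np.ndarray, masses: np.ndarray | None = None
) -> float:
    """Mass-weighted radius of gyration, sqrt(sum m |r - r_com|^2 / sum m)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one atom")
    n = coords.shape[0]
    m = np.ones(n) if masses is None else np.asarray(masses, dtype=float)
    total = m.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (m @ coords) / total
    d2 = np.einsum("ij,ij->i", coords - com, coords - com)
    return float(np.sqrt((m @ d2) / total))


def gyration_series(
    traj: Trajectory, sel: Selection | None = None
) -> GyrationSeries:
    """Per-frame radius of gyration over selected atoms (default: all)."""
    if sel is None:
        idx = np.arange(traj.n_atoms)
        masses = traj.masses()
    else:
        if len(sel) == 0:
            raise ValueError("empty selection")
        idx = sel.as_array()
        masses = traj.masses(sel.indices)
    values = np.array(
        [radius_of_gyration(traj.coords[f, idx], masses) for f in range(traj.n_frames)]
    )
    return GyrationSeries(values=values)


def pca_modes(
    traj: Trajectory,
    sel: Selection,
    n_modes: int | None = None,
    reference_frame: int = 0,
) -> PCAResult:
    """PCA of selected-atom coordinates after superposition onto a reference.

    Modes are eigenvectors of the (3n x 3n) covariance of superposed,
    centered coordinates, returned in descending variance order.
    """
    if len(sel) == 0:
        raise ValueError("empty selection")
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames for PCA")
    idx = sel.as_array()
    n_dof = 3 * len(idx)
    if n_modes is None:
        n_modes = min(n_dof, traj.n_frames)
    if n_modes > n_dof:
        raise ValueError(f"n_modes {n_modes} exceeds 3 * n_atoms = {n_dof}")

    ref = traj.coords[reference_frame, idx]
    fitted = np.empty((traj.n_frames, len(idx), 3))
    for f in range(traj.n_frames):
        sup = kabsch_superpose(traj.coords[f, idx], ref)
        fitted[f] = apply_superposition(traj.coords[f, idx], sup)

    flat = fitted.reshape(traj.n_frames, n_dof)
    mean = flat.mean(axis=0)
    centered = flat - mean
    cov = centered.T @ centered / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # Deterministic sign: largest-magnitude component positive.
    for k in range(evecs.shape[1]):
        peak = np.argmax(np.abs(evecs[:, k]))
        if evecs[peak, k] < 0:
            evecs[:, k] = -evecs[:, k]

    modes = evecs[:, :n_modes].T
    projections = centered @ modes.T
    return PCAResult(
        mean=mean.reshape(-1, 3),
        modes=modes,
        variances=evals[:n_modes],
        projections=projections,
        total_variance=float(np.trace(cov)),
    )
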