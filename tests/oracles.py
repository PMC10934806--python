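"""Independent reference implementations used to check the package.

These deliberately avoid the code paths they validate: the RMSD oracle
uses the quaternion eigenvalue method (no SVD), the clustering oracle is
a naive loop-based reimplementation of the greedy rule, and the contact
map oracle recounts per frame with explicit loops.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD via the Horn quaternion eigenvalue method."""
    p = np.asarray(mobile, float)
    q = np.asarray(reference, float)
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    n = p.shape[0]
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k).max()
    gp = float(np.einsum("ij,ij->", p, p))
    gq = float(np.einsum("ij,ij->", q, q))
    return float(np.sqrt(max(0.0, (gp + gq - 2.0 * lam) / n)))


def greedy_cluster_reference(rmsd: np.ndarray, cutoff: float):
    """Naive reimplementation of GROMOS greedy neighbour clustering.

    Returns (assignment array, populations, representatives) with the
    same tie rules: lowest frame index wins.
    """
    n = rmsd.shape[0]
    remaining = set(range(n))
    assignment = [-1] * n
    populations = []
    representatives = []
    cid = 0
    while remaining:
        best_centre, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining if rmsd[i][j] <= cutoff)
            if count > best_count:
                best_centre, best_count = i, count
        members = sorted(j for j in remaining if rmsd[best_centre][j] <= cutoff)
        best_rep, best_mean = None, None
        for i in members:
            if len(members) == 1:
                mean = 0.0
            else:
                mean = sum(rmsd[i][j] for j in members if j != i) / (len(members) - 1)
            if best_mean is None or mean < best_mean:
                best_rep, best_mean = i, mean
        for j in members:
            assignment[j] = cid
            remaining.discard(j)
        populations.append(len(members))
        representatives.append(best_rep)
        cid += 1
    return np.array(assignment), populations, representatives


def contact_map_reference(ca_coords: np.ndarray, cutoff: float) -> np.ndarray:
    """Per-frame recount of CA contact frequencies with explicit loops."""
    n_frames, n_res, _ = ca_coords.shape
    counts = np.zeros((n_res, n_res))
    for f in range(n_frames):
        for i in range(n_res):
            for j in range(n_res):
                d = np.sqrt(((ca_coords[f, i] - ca_coords[f, j]) ** 2).sum())
                if d <= cutoff:
                    counts[i, j] += 1
    return counts / n_frames


def random_rigid_motion(rng: np.random.Generator):
    """A uniform-ish random proper rotation plus a random translation."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-20.0, 20.0, 3)
    return q, t
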