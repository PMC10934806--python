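import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conformetrics import synthetic as syn
from conformetrics.geometry import (
    gyration_series,
    kabsch_superpose,
    pca_modes,
    radius_of_gyration,
    rmsd_all_to_all,
)
from conformetrics.structio import Trajectory, select

from .oracles import quaternion_rmsd, random_rigid_motion


class TestKabsch:
    def test_self_superposition_is_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(30, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-8)

    def test_recovers_rotation_and_translation(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(25, 3))
        rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        mobile = ref @ rot90.T + np.array([1.0, 2.0, 3.0])
        res = kabsch_superpose(mobile, ref)
        assert res.rmsd <= 1e-9
        # Recovered transform inverts the applied one.
        assert np.allclose(res.rotation, rot90.T, atol=1e-8)
        restored = mobile @ res.rotation.T + res.translation
        assert np.allclose(restored, ref, atol=1e-8)

    def test_matches_quaternion_oracle_with_noise(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(100, 3)) * 5
        q, t = random_rigid_motion(rng)
        mobile = ref @ q.T + t + rng.normal(0.0, 0.5, ref.shape)
        res = kabsch_superpose(mobile, ref)
        assert res.rmsd == pytest.approx(quaternion_rmsd(mobile, ref), abs=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_inputs_still_proper_rotation(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        res = kabsch_superpose(line, line + 1.0)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_weights_equal_unweighted(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 40, 3))
        unweighted = kabsch_superpose(a, b).rmsd
        weighted = kabsch_superpose(a, b, weights=np.full(40, 2.5)).rmsd
        assert weighted == pytest.approx(unweighted, abs=1e-12)


class TestRmsdMatrix:
    def test_identical_frames_zero_matrix(self, ab42_topology):
        frame = syn.helix_frame(syn.AB42_SEQUENCE)
        traj = Trajectory(topology=ab42_topology, coords=np.stack([frame] * 3))
        m = rmsd_all_to_all(traj, select(traj, atom_names={"CA"}))
        assert np.abs(m).max() <= 1e-9

    def test_rigid_copy_pattern(self, ab42_topology):
        rng = np.random.default_rng(4)
        a = syn.helix_frame(syn.AB42_SEQUENCE)
        q, t = random_rigid_motion(rng)
        b = syn.extended_frame(syn.AB42_SEQUENCE)
        traj = Trajectory(topology=ab42_topology, coords=np.stack([a, a @ q.T + t, b]))
        m = rmsd_all_to_all(traj, select(traj, atom_names={"CA"}))
        assert m[0, 1] <= 1e-9
        assert m[0, 2] == pytest.approx(m[1, 2], abs=1e-9)
        assert m[0, 2] > 1.0

    def test_matches_bruteforce_oracle(self, ab42_topology):
        rng = np.random.default_rng(5)
        spec = syn.MonomerEnsembleSpec(weights={"coil": 1.0}, n_frames=20, seed=6)
        traj, _ = syn.make_monomer_ensemble(spec)
        sel = select(traj, atom_names={"CA"})
        m = rmsd_all_to_all(traj, sel)
        assert np.allclose(m, m.T, atol=1e-10)
        assert np.abs(np.diag(m)).max() == 0.0
        ca = traj.coords[:, sel.as_array(), :]
        for i in range(20):
            for j in range(i + 1, 20):
                assert m[i, j] == pytest.approx(quaternion_rmsd(ca[i], ca[j]), abs=1e-6)

    def test_empty_selection_errors(self, helix_traj):
        with pytest.raises(ValueError):
            rmsd_all_to_all(helix_traj, select(helix_traj, atom_names={"ZZ"}, allow_empty=True))


class TestGyration:
    def test_two_unit_masses(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(1.0)

    def test_unit_square(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        assert radius_of_gyration(coords) == pytest.approx(np.sqrt(0.5))

    def test_rigid_invariance(self, helix_traj):
        rng = np.random.default_rng(7)
        sel = select(helix_traj, atom_names={"CA"})
        masses = helix_traj.masses(sel.indices)
        base = radius_of_gyration(helix_traj.coords[0, sel.as_array()], masses)
        q, t = random_rigid_motion(rng)
        moved = helix_traj.coords[0, sel.as_array()] @ q.T + t
        assert radius_of_gyration(moved, masses) == pytest.approx(base, abs=1e-10)

    def test_zero_mass_errors(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((2, 3)), masses=np.zeros(2))

    def test_series_stats(self, static_fibril):
        series = gyration_series(static_fibril)
        assert len(series.values) == static_fibril.n_frames
        assert series.sd == pytest.approx(0.0, abs=1e-9)
        assert series.mean > 0


class TestPCA:
    def _single_atom_traj(self):
        topo = syn.monomer_topology("AAAAA")
        base = syn.extended_frame("AAAAA")
        frames = []
        ca_index = 1  # CA of residue 1
        for k in range(12):
            f = base.copy()
            f[ca_index, 0] += 0.5 * k
            frames.append(f)
        return Trajectory(topology=topo, coords=np.stack(frames)), ca_index

    def test_single_moving_atom_mode(self):
        traj, _ = self._single_atom_traj()
        # Select only CA atoms; superposition would absorb part of the motion
        # of a tiny selection, so use all atoms as reference-stable anchor.
        sel = select(traj, atom_names={"CA", "N", "C", "O", "CB"})
        res = pca_modes(traj, sel, n_modes=3)
        assert res.variance_fractions[0] >= 0.99

    def test_variance_conservation(self):
        spec = syn.MonomerEnsembleSpec(weights={"u": 1.0}, noise=0.5, n_frames=15, seed=8)
        traj, _ = syn.make_monomer_ensemble(spec)
        sel = select(traj, atom_names={"CA"})
        res = pca_modes(traj, sel, n_modes=min(3 * len(sel), traj.n_frames))
        assert res.variances.sum() == pytest.approx(res.total_variance, rel=1e-8)
        # Modes orthonormal.
        gram = res.modes @ res.modes.T
        assert np.allclose(gram, np.eye(len(res.variances)), atol=1e-8)

    def test_reconstruction_with_all_modes(self):
        from conformetrics.geometry import apply_superposition

        spec = syn.MonomerEnsembleSpec(weights={"u": 1.0}, noise=0.3, n_frames=10, seed=9)
        traj, _ = syn.make_monomer_ensemble(spec)
        sel = select(traj, res_range=(1, 4), atom_names={"CA", "N", "C"})
        res = pca_modes(traj, sel, n_modes=3 * len(sel))
        recon = res.projections @ res.modes + res.mean.ravel()
        idx = sel.as_array()
        fitted = np.stack(
            [
                apply_superposition(
                    traj.coords[f, idx],
                    kabsch_superpose(traj.coords[f, idx], traj.coords[0, idx]),
                ).ravel()
                for f in range(traj.n_frames)
            ]
        )
        scale = max(np.linalg.norm(fitted), 1.0)
        assert np.linalg.norm(recon - fitted) <= 1e-6 * scale

    def test_isotropic_noise_leading_fraction(self):
        # Isotropic noise on a compact cloud: leading fraction ~ 1/(3n),
        # inflated by the Marchenko-Pastur sampling edge over the ~3n - 6
        # dimensions that survive the rigid-body fit.
        rng = np.random.default_rng(10)
        n_atoms, n_frames = 20, 1500
        base = rng.normal(0.0, 3.0, (n_atoms, 3))
        coords = base[None] + rng.normal(0.0, 0.1, (n_frames, n_atoms, 3))
        topo = syn.monomer_topology("AAAAA")[:n_atoms]
        traj = Trajectory(topology=topo, coords=coords)
        sel = select(traj, atom_names={"N", "CA", "C", "O", "CB"})
        res = pca_modes(traj, sel, n_modes=1)
        d = 3 * n_atoms
        mp_upper = (1 + np.sqrt(d / n_frames)) ** 2 / (d - 6)
        assert 1.0 / d <= res.variance_fractions[0] <= 1.15 * mp_upper

    def test_hinge_motion_dominates_spectrum(self):
        spec = syn.FibrilSpec(
            n_frames=40, dve_targets=np.linspace(30, 25, 40), noise=0.1, seed=11
        )
        traj, _ = syn.make_fibril(spec)
        sel = select(traj, atom_names={"CA"})
        res = pca_modes(traj, sel, n_modes=1)
        assert res.variance_fractions[0] >= 0.8

    def test_n_modes_bound(self, helix_traj):
        spec = syn.MonomerEnsembleSpec(weights={"u": 1.0}, noise=0.1, n_frames=4, seed=1)
        traj, _ = syn.make_monomer_ensemble(spec)
        sel = select(traj, res_range=(1, 2), atom_names={"CA"})
        with pytest.raises(ValueError):
            pca_modes(traj, sel, n_modes=3 * len(sel) + 1)


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_rog_and_rmsd_rigid_invariance_property(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(12, 3)) * 4
    q, t = random_rigid_motion(rng)
    moved = pts @ q.T + t
    assert radius_of_gyration(moved) == pytest.approx(radius_of_gyration(pts), abs=1e-9)
    assert kabsch_superpose(moved, pts).rmsd <= 1e-9
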