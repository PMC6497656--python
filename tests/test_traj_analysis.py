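"""Superposition, RMSD/Rg/RMSF, H-bond series and distance matrices."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pocketpipe.structio import AtomRecord, Structure
from pocketpipe.synthetic import RigidMotion, SyntheticSpec, make_toy_structure, make_trajectory
from pocketpipe.traj_analysis import (
    FitError,
    Trajectory,
    hbond_series,
    kabsch_superpose,
    mean_smallest_distance_matrix,
    read_trajectory,
    resolve_selection,
    rg_series,
    rmsd,
    rmsd_series,
    rmsf_per_residue,
)


def rigid(coords, angles=(20, -35, 70), shift=(3.0, -1.0, 5.0)):
    rot = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
    return coords @ rot.T + np.asarray(shift)


def two_atom_structure():
    atoms = [
        AtomRecord(1, "CA", "C", "A", "ALA", 1, coords=np.array([0.0, 0.0, 0.0])),
        AtomRecord(2, "CA", "C", "A", "ALA", 2, coords=np.array([2.0, 0.0, 0.0])),
        AtomRecord(3, "CA", "C", "A", "ALA", 3, coords=np.array([0.0, 2.0, 0.0])),
    ]
    return Structure(model_id=1, atoms=atoms)


class TestKabsch:
    def test_identity_on_equal_inputs(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        rot, trans, fitted = kabsch_superpose(x, x)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-10)
        np.testing.assert_allclose(fitted, x, atol=1e-10)

    def test_recovers_rigid_transform_exactly(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 3))
        rot, _, fitted = kabsch_superpose(x, rigid(x))
        assert rmsd(x, fitted) < 1e-10
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_noise_fit_never_worse_than_unfitted(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 3))
        y = rigid(x) + rng.normal(0, 0.2, size=x.shape)
        _, _, fitted = kabsch_superpose(x, y)
        assert rmsd(x, fitted) <= rmsd(x, y)

    def test_weighted_fit_prioritizes_heavy_atoms(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20, 3))
        y = x.copy()
        y[0] += 5.0  # outlier
        w = np.ones(20)
        w[0] = 1e-9
        _, _, fitted = kabsch_superpose(x, y, weights=w)
        np.testing.assert_allclose(fitted[1:], x[1:], atol=1e-6)

    @pytest.mark.parametrize(
        "ref,mob",
        [
            (np.zeros((2, 3)), np.zeros((2, 3))),  # too few atoms
            (np.outer(np.arange(5.0), [1, 0, 0]), np.random.default_rng(0).normal(size=(5, 3))),
        ],
    )
    def test_degenerate_inputs_rejected(self, ref, mob):
        with pytest.raises(FitError):
            kabsch_superpose(ref, mob)


class TestRmsdSeries:
    def test_identical_frames_zero(self):
        s = two_atom_structure()
        frames = np.repeat(s.coords_array()[None], 4, axis=0)
        out = rmsd_series(Trajectory(s, frames), selection="calpha")
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_rigid_motion_fits_to_zero(self):
        spec = SyntheticSpec(seed=5, n_residues=20, n_frames=10, noise_sigma=0.0)
        traj = make_trajectory(spec, make_toy_structure(spec))
        out = rmsd_series(traj, "backbone")
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_known_displacement_closed_form(self):
        # 3 in-plane atoms; one displaced out of plane by d cannot be
        # reduced below the optimal-fit closed form; verify against a
        # numeric oracle by brute sampling of rotations.
        s = two_atom_structure()
        base = s.coords_array()
        moved = base.copy()
        moved[2, 2] += 1.0
        frames = np.stack([base, moved])
        out = rmsd_series(Trajectory(s, frames), selection="calpha")
        _, _, fitted = kabsch_superpose(base, moved)
        assert out[1] == pytest.approx(rmsd(base, fitted) / 10.0, rel=1e-10)
        assert out[1] <= rmsd(base, moved) / 10.0
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_bad_reference_index(self):
        s = two_atom_structure()
        frames = np.repeat(s.coords_array()[None], 2, axis=0)
        with pytest.raises(IndexError):
            rmsd_series(Trajectory(s, frames), "calpha", reference_frame=5)


class TestRgSeries:
    def test_two_equal_mass_points_two_angstrom_apart(self):
        atoms = [
            AtomRecord(1, "CA", "C", "A", "GLY", 1, coords=np.array([0.0, 0.0, 0.0])),
            AtomRecord(2, "CA", "C", "A", "GLY", 2, coords=np.array([2.0, 0.0, 0.0])),
        ]
        s = Structure(model_id=1, atoms=atoms)
        out = rg_series(Trajectory(s, s.coords_array()[None]), selection="calpha")
        assert out[0] == pytest.approx(0.1)  # 1 Å from COM = 0.1 nm

    def test_coincident_atoms_zero(self):
        atoms = [
            AtomRecord(i + 1, "CA", "C", "A", "GLY", i + 1, coords=np.zeros(3)) for i in range(4)
        ]
        s = Structure(model_id=1, atoms=atoms)
        assert rg_series(Trajectory(s, s.coords_array()[None]))[0] == 0.0

    def test_matches_direct_formula_on_random_cloud(self):
        rng = np.random.default_rng(7)
        n = 100
        atoms = [
            AtomRecord(i + 1, "CA", "C", "A", "GLY", i + 1, coords=rng.normal(size=3) * 5)
            for i in range(n)
        ]
        s = Structure(model_id=1, atoms=atoms)
        out = rg_series(Trajectory(s, s.coords_array()[None]), mass_weighted=False)
        xyz = s.coords_array()
        com = xyz.mean(axis=0)
        direct = math.sqrt(np.sum((xyz - com) ** 2) / n) / 10.0
        assert out[0] == pytest.approx(direct, rel=1e-12)

    def test_unweighted_regular_polygon_equals_circumradius(self):
        # All vertices of a regular polygon lie at the circumradius from COM.
        k, radius = 8, 3.0
        ang = 2 * np.pi * np.arange(k) / k
        atoms = [
            AtomRecord(i + 1, "CA", "C", "A", "GLY", i + 1,
                       coords=np.array([radius * np.cos(t), radius * np.sin(t), 0.0]))
            for i, t in enumerate(ang)
        ]
        s = Structure(model_id=1, atoms=atoms)
        out = rg_series(Trajectory(s, s.coords_array()[None]), mass_weighted=False)
        assert out[0] == pytest.approx(radius / 10.0, rel=1e-12)


class TestRmsf:
    def test_static_trajectory_all_zero(self):
        spec = SyntheticSpec(seed=6, n_residues=10, n_frames=5, noise_sigma=0.0,
                             rigid_motion=RigidMotion(0.0, 0.0))
        traj = make_trajectory(spec, make_toy_structure(spec))
        _, out = rmsf_per_residue(traj)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_two_state_oscillation_equals_displacement(self):
        # One residue hops ±d between two states, equal time in each:
        # its RMSF about the mean is d. The global fit soaks up a small
        # fraction of the hop (the moving atoms are 4 of 400 fitted atoms),
        # so the identity holds to a few percent in a large system.
        spec = SyntheticSpec(seed=8, n_residues=100, n_frames=4, noise_sigma=0.0,
                             rigid_motion=RigidMotion(0.0, 0.0))
        s = make_toy_structure(spec)
        base = s.coords_array()
        idx = resolve_selection(s, "backbone")
        res_atoms = [i for i in idx if s.atoms[i].res_seq == 50]
        d = 0.8  # Å
        frames = np.repeat(base[None], 4, axis=0)
        for t in range(4):
            sign = 1.0 if t % 2 == 0 else -1.0
            frames[t, res_atoms, 0] += sign * d
        rids, out = rmsf_per_residue(Trajectory(s, frames), "backbone")
        per_res = dict(zip([r[1] for r in rids], out))
        assert per_res[50] == pytest.approx(d / 10.0, rel=0.05)
        others = [v for k, v in per_res.items() if k != 50]
        assert max(others) < 0.02 * d / 10.0

    def test_single_frame_rejected(self):
        s = two_atom_structure()
        with pytest.raises(ValueError):
            rmsf_per_residue(Trajectory(s, s.coords_array()[None]))


class TestHbondSeries:
    def _traj(self, within):
        """Donor/acceptor pair inside criteria in the given frame mask."""
        donor = AtomRecord(1, "OG", "O", "A", "SER", 1, coords=np.array([0.0, 0.0, 0.0]))
        h = AtomRecord(2, "HG", "H", "A", "SER", 1, coords=np.array([1.0, 0.0, 0.0]))
        acc = AtomRecord(3, "O1", "O", "L", "LIG", 9, coords=np.array([2.9, 0.0, 0.0]), is_hetero=True)
        extra = AtomRecord(4, "CA", "C", "A", "SER", 1, coords=np.array([-1.5, 0.0, 0.0]))
        s = Structure(model_id=1, atoms=[donor, h, acc, extra])
        base = s.coords_array()
        frames = np.repeat(base[None], len(within), axis=0)
        for t, ok in enumerate(within):
            if not ok:
                frames[t, 2, 0] = 6.0  # move acceptor out of range
        return Trajectory(s, frames)

    def test_occupancy_fraction(self):
        mask = [True] * 7 + [False] * 3
        traj = self._traj(mask)
        counts, occ = hbond_series(traj, [("A", 1, "", "OG")], [("L", 9, "", "O1")])
        np.testing.assert_array_equal(counts, np.array(mask, dtype=int))
        assert occ[(("A", 1, "", "OG"), ("L", 9, "", "O1"))] == pytest.approx(0.7)

    def test_never_within_cutoff_all_zero(self):
        traj = self._traj([False] * 5)
        counts, occ = hbond_series(traj, [("A", 1, "", "OG")], [("L", 9, "", "O1")])
        assert counts.sum() == 0 and occ == {}

    def test_exact_boundary_counted(self):
        traj = self._traj([True])
        traj.frames[0, 2, 0] = 3.5
        counts, _ = hbond_series(traj, [("A", 1, "", "OG")], [("L", 9, "", "O1")])
        assert counts[0] == 1


class TestMdmat:
    def test_single_frame_known_distance(self):
        a1 = AtomRecord(1, "CA", "C", "A", "GLY", 1, coords=np.array([0.0, 0.0, 0.0]))
        a2 = AtomRecord(2, "CB", "C", "A", "ALA", 2, coords=np.array([5.0, 0.0, 0.0]))
        a3 = AtomRecord(3, "CA", "C", "A", "ALA", 2, coords=np.array([7.0, 0.0, 0.0]))
        s = Structure(model_id=1, atoms=[a1, a2, a3])
        _, mat, _, _ = mean_smallest_distance_matrix(Trajectory(s, s.coords_array()[None]))
        assert mat[0, 1] == pytest.approx(0.5)  # closest atoms 5 Å = 0.5 nm

    def test_truncation_caps_far_pairs(self):
        a1 = AtomRecord(1, "CA", "C", "A", "GLY", 1, coords=np.array([0.0, 0.0, 0.0]))
        a2 = AtomRecord(2, "CA", "C", "A", "GLY", 2, coords=np.array([20.0, 0.0, 0.0]))
        s = Structure(model_id=1, atoms=[a1, a2])
        _, mat, agg_mean, _ = mean_smallest_distance_matrix(Trajectory(s, s.coords_array()[None]))
        assert mat[0, 1] == pytest.approx(1.5)
        assert agg_mean == pytest.approx(1.5)

    def test_matches_bruteforce_oracle_and_symmetry(self):
        spec = SyntheticSpec(seed=9, n_residues=8, n_frames=4, noise_sigma=0.3)
        s = make_toy_structure(spec)
        traj = make_trajectory(spec, s)
        rids, mat, agg_mean, agg_sum = mean_smallest_distance_matrix(traj)
        # Brute-force double-loop oracle over frames/residues/atom pairs.
        groups = [
            [i for i in s.residue_index[r] if not s.atoms[i].is_hydrogen] for r in rids
        ]
        n = len(rids)
        expect = np.zeros((n, n))
        for t in range(traj.n_frames):
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    best = min(
                        np.linalg.norm(traj.frames[t][p] - traj.frames[t][q])
                        for p in groups[i]
                        for q in groups[j]
                    )
                    expect[i, j] += min(best, 15.0)
        expect /= traj.n_frames * 10.0
        np.testing.assert_allclose(mat, expect, atol=1e-12)
        np.testing.assert_allclose(mat, mat.T, atol=0)
        assert mat.diagonal().max() == 0.0
        assert agg_sum == pytest.approx(mat.sum())


class TestRigidInvariance:
    def test_all_metrics_invariant_under_global_transform(self):
        spec = SyntheticSpec(seed=10, n_residues=15, n_frames=6, noise_sigma=0.2)
        s = make_toy_structure(spec)
        traj = make_trajectory(spec, s)
        moved = Trajectory(s, np.stack([rigid(f) for f in traj.frames]), times=traj.times)
        np.testing.assert_allclose(
            rmsd_series(traj, "backbone"), rmsd_series(moved, "backbone"), atol=1e-9
        )
        np.testing.assert_allclose(rg_series(traj), rg_series(moved), atol=1e-9)
        np.testing.assert_allclose(
            rmsf_per_residue(traj)[1], rmsf_per_residue(moved)[1], atol=1e-9
        )
        np.testing.assert_allclose(
            mean_smallest_distance_matrix(traj)[1],
            mean_smallest_distance_matrix(moved)[1],
            atol=1e-9,
        )


class TestTrajectoryIO:
    def test_multi_model_roundtrip(self, tmp_path):
        from pocketpipe.structio import write_pdb

        spec = SyntheticSpec(seed=12, n_residues=6, n_frames=3, noise_sigma=0.1)
        s = make_toy_structure(spec)
        traj = make_trajectory(spec, s)
        models = []
        for t in range(traj.n_frames):
            atoms = [
                AtomRecord(a.serial, a.atom_name, a.element, a.chain_id, a.res_name,
                           a.res_seq, a.insertion_code, traj.frames[t][i], a.is_hetero)
                for i, a in enumerate(s.atoms)
            ]
            models.append(Structure(model_id=t + 1, atoms=atoms))
        path = tmp_path / "traj.pdb"
        write_pdb(models, path)
        back = read_trajectory(path)
        assert back.n_frames == 3
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-3)
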