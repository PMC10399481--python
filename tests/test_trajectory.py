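"""Kabsch superposition, RMSD series and per-residue RMSF."""

import numpy as np
import pytest

from dualphore.geometry import apply_rigid, kabsch_superpose, random_rotation, raw_rmsd
from dualphore.synthetic import GeneratorSpec, TrajectorySpec, gen_trajectory
from dualphore.trajectory import (
    AtomMeta,
    Trajectory,
    read_trajectory,
    rmsd_series,
    rmsf_per_residue,
    write_trajectory_pdb,
)

from oracles import grid_min_rmsd, superpose_rmsd_scipy

SIGMA = 0.3
EXPECTED_3D = SIGMA * np.sqrt(3.0)


def _core(meta: AtomMeta) -> bool:
    return 10 <= meta.residue_index <= 190


@pytest.fixture(scope="module")
def jitter_traj() -> Trajectory:
    return gen_trajectory(
        GeneratorSpec(
            seed=21,
            trajectory=TrajectorySpec(
                n_atoms=200, n_frames=100, core_sigma=SIGMA, terminal_multiplier=5.0
            ),
        )
    )


class TestKabsch:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        angle = np.deg2rad(30.0)
        known = np.array(
            [
                [np.cos(angle), -np.sin(angle), 0.0],
                [np.sin(angle), np.cos(angle), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        shift = np.array([1.0, -2.0, 3.0])
        moved = apply_rigid(pts, known, shift)
        rot, trans, rmsd = kabsch_superpose(pts, moved)
        np.testing.assert_allclose(rot, known, atol=1e-6)
        np.testing.assert_allclose(trans, shift, atol=1e-6)
        assert rmsd < 1e-10

    def test_mirror_image_not_matched(self):
        """Reflections are rejected; the residual equals the best proper rotation."""
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(4, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        _, _, rmsd = kabsch_superpose(mirrored, pts)
        assert rmsd > 0.1
        grid = grid_min_rmsd(mirrored, pts, n=200_000, seed=3)
        assert rmsd <= grid + 1e-12
        assert grid - rmsd < 0.05  # dense sampling approaches the true optimum

    def test_agrees_with_scipy_on_random_sets(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            a = rng.normal(size=(6, 3)) * rng.uniform(0.5, 3.0)
            b = rng.normal(size=(6, 3)) * rng.uniform(0.5, 3.0)
            _, _, rmsd = kabsch_superpose(a, b)
            _, expected = superpose_rmsd_scipy(a, b)
            assert rmsd == pytest.approx(expected, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self):
        traj = gen_trajectory(
            GeneratorSpec(seed=0, trajectory=TrajectorySpec(n_atoms=30, n_frames=5, core_sigma=0.0))
        )
        out = rmsd_series(traj)
        assert np.allclose(out["rmsd_A"], 0.0)
        np.testing.assert_allclose(out["time_ps"], np.arange(5) * 10.0)

    def test_rigid_rotations_vanish_under_superposition(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(30, 3)) * 5.0
        frames = [base]
        for _ in range(4):
            frames.append(apply_rigid(base, random_rotation(rng), rng.normal(size=3)))
        meta = [AtomMeta("CA", i + 1, "ALA", True) for i in range(30)]
        traj = Trajectory(meta, np.array(frames))
        assert rmsd_series(traj, superpose=True)["rmsd_A"].max() <= 1e-6
        assert rmsd_series(traj, superpose=False)["rmsd_A"].max() > 1.0

    def test_isotropic_jitter_closed_form(self, jitter_traj):
        """Per-coordinate sigma gives mean RMSD ~ sigma*sqrt(3) off the clean frame."""
        out = rmsd_series(jitter_traj, superpose=False, selection=_core)
        mean = out["rmsd_A"][1:].mean()  # frame 0 is the clean reference
        assert mean == pytest.approx(EXPECTED_3D, rel=0.05)

    def test_superposed_never_exceeds_in_place(self, jitter_traj):
        sup = rmsd_series(jitter_traj, superpose=True)["rmsd_A"]
        raw = rmsd_series(jitter_traj, superpose=False)["rmsd_A"]
        assert np.all(sup <= raw + 1e-9)

    def test_invariant_to_global_rigid_transform(self, jitter_traj):
        rng = np.random.default_rng(6)
        rot = random_rotation(rng)
        trans = rng.normal(0, 20, 3)
        moved = Trajectory(
            jitter_traj.atom_meta,
            np.array([apply_rigid(f, rot, trans) for f in jitter_traj.frames]),
            jitter_traj.frame_interval_ps,
        )
        a = rmsd_series(jitter_traj, superpose=True)["rmsd_A"]
        b = rmsd_series(moved, superpose=True)["rmsd_A"]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_empty_selection_rejected(self, jitter_traj):
        with pytest.raises(ValueError, match="empty"):
            rmsd_series(jitter_traj, selection=lambda m: False)


class TestRmsf:
    def test_static_trajectory_zero_everywhere(self):
        traj = gen_trajectory(
            GeneratorSpec(seed=0, trajectory=TrajectorySpec(n_atoms=30, n_frames=5, core_sigma=0.0))
        )
        assert rmsf_per_residue(traj)["rmsf_A"].max() == pytest.approx(0.0, abs=1e-12)

    def test_single_frame_rejected(self):
        traj = gen_trajectory(
            GeneratorSpec(seed=0, trajectory=TrajectorySpec(n_atoms=30, n_frames=1, core_sigma=0.0))
        )
        with pytest.raises(ValueError, match="two frames"):
            rmsf_per_residue(traj)

    def test_jitter_closed_form_on_core(self, jitter_traj):
        out = rmsf_per_residue(jitter_traj)
        core = out[(out.residue_index >= 10) & (out.residue_index <= 190)]
        assert core["rmsf_A"].mean() == pytest.approx(EXPECTED_3D, rel=0.10)

    def test_floppy_termini_exceed_rigid_core(self, jitter_traj):
        """Terminal residues carry 5x jitter and must show higher RMSF."""
        out = rmsf_per_residue(jitter_traj).set_index("residue_index")["rmsf_A"]
        termini = list(range(1, 6)) + list(range(196, 201))
        core = list(range(50, 151))
        assert out.loc[termini].min() > out.loc[core].max()

    def test_invariant_to_frame_permutation(self, jitter_traj):
        rng = np.random.default_rng(8)
        perm = rng.permutation(jitter_traj.n_frames)
        shuffled = Trajectory(
            jitter_traj.atom_meta,
            jitter_traj.frames[perm],
            jitter_traj.frame_interval_ps,
        )
        a = rmsf_per_residue(jitter_traj)["rmsf_A"].to_numpy()
        b = rmsf_per_residue(shuffled)["rmsf_A"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestTrajectoryIO:
    def test_multi_model_pdb_round_trip(self, tmp_path):
        traj = gen_trajectory(
            GeneratorSpec(seed=9, trajectory=TrajectorySpec(n_atoms=25, n_frames=4))
        )
        path = tmp_path / "traj.pdb"
        write_trajectory_pdb(traj, path)
        assert path.read_text().count("MODEL") >= 4
        back = read_trajectory(path, frame_interval_ps=10.0)
        assert back.n_frames == traj.n_frames
        assert back.n_atoms == traj.n_atoms
        assert all(m.is_alpha_carbon for m in back.atom_meta)
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-2)  # PDB 3 dp

    def test_xyz_trajectory_read(self, tmp_path):
        frames = np.arange(2 * 4 * 3, dtype=float).reshape(2, 4, 3) / 10.0
        lines = []
        for f in frames:
            lines.append("4")
            lines.append("frame")
            for xyz in f:
                lines.append("C %.4f %.4f %.4f" % tuple(xyz))
        path = tmp_path / "traj.xyz"
        path.write_text("\n".join(lines) + "\n")
        traj = read_trajectory(path, frame_interval_ps=5.0)
        assert traj.n_frames == 2 and traj.n_atoms == 4
        np.testing.assert_allclose(traj.frames, frames, atol=1e-4)
        np.testing.assert_allclose(traj.times_ps(), [0.0, 5.0])
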