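import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from conftest import oracle_components, random_poses, traj_from_poses
from mbgag.gag_models import MBMolecule, Pose
from mbgag.stack_analysis import (
    ANTIPARALLEL,
    INDETERMINATE,
    PARALLEL,
    DegenerateGeometryError,
    classify_orientation,
    detect_stacks,
    fit_ring_plane,
    interplane_distance,
    mb_plane,
    stack_statistics,
)
from mbgag.synthetic_traj import generate_scripted, stack_scenario

I3 = np.eye(3)


def plane_at(rot=I3, t=(0.0, 0.0, 0.0), template=None):
    template = template or MBMolecule.template()
    pose = Pose(np.asarray(rot, float), np.asarray(t, float))
    return mb_plane("MB", pose.apply(template.ring_atoms),
                    pose.apply(template.terminal_nitrogens))


class TestFitRingPlane:
    def test_exactly_coplanar_points_have_zero_residual(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        centroid, normal = fit_ring_plane(pts)
        residuals = (pts - centroid) @ normal
        assert np.abs(residuals).max() < 1e-12
        assert np.linalg.norm(normal) == pytest.approx(1.0)

    @given(seed=st.integers(0, 10**6))
    @settings(deadline=None, max_examples=50)
    def test_equivariance_under_rotation(self, seed):
        """Rotating the points rotates the fitted normal (up to sign)."""
        template = MBMolecule.template()
        rot = Rotation.random(random_state=np.random.default_rng(seed)).as_matrix()
        _, n0 = fit_ring_plane(template.ring_atoms)
        _, n1 = fit_ring_plane(template.ring_atoms @ rot.T)
        expected = rot @ n0
        assert min(np.linalg.norm(n1 - expected),
                   np.linalg.norm(n1 + expected)) < 1e-9

    def test_noisy_plane_normal_recovery(self):
        """Gaussian noise sigma 0.05 A on 12 coplanar points: fitted normal
        within 2 degrees of truth in at least 95 of 100 seeded runs."""
        rng = np.random.default_rng(12345)
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.stack([2 * np.cos(theta), 2 * np.sin(theta),
                        np.zeros(12)], axis=1)
        hits = 0
        for _ in range(100):
            noisy = pts + rng.normal(0, 0.05, pts.shape)
            _, n = fit_ring_plane(noisy)
            angle = np.degrees(np.arccos(min(1.0, abs(n[2]))))
            hits += angle < 2.0
        assert hits >= 95

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], float)
        with pytest.raises(DegenerateGeometryError):
            fit_ring_plane(pts)


class TestInterplaneDistance:
    def test_parallel_offset_along_normal(self):
        a = plane_at()
        b = plane_at(t=(0, 0, 3.7))
        assert interplane_distance(a, b) == pytest.approx(3.7, abs=1e-12)

    def test_identical_poses_give_zero(self):
        assert interplane_distance(plane_at(), plane_at()) == 0.0

    def test_pure_inplane_offset_gives_zero(self):
        assert interplane_distance(
            plane_at(), plane_at(t=(5.0, 0, 0))
        ) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_in_arguments(self):
        rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        a, b = plane_at(), plane_at(rot, (1.0, 2.0, 3.5))
        assert interplane_distance(a, b) == interplane_distance(b, a)


class TestClassifyOrientation:
    def test_translated_copy_is_parallel(self):
        assert classify_orientation(plane_at(), plane_at(t=(0, 0, 3.7))) == PARALLEL

    def test_flip_about_normal_is_antiparallel(self):
        flip = np.diag([-1.0, -1.0, 1.0])  # 180 degrees about z
        assert classify_orientation(plane_at(), plane_at(flip)) == ANTIPARALLEL

    def test_quarter_turn_is_indeterminate(self):
        quarter = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        assert classify_orientation(plane_at(), plane_at(quarter)) == INDETERMINATE

    def test_symmetric_under_swap(self):
        rot = Rotation.from_euler("z", 120, degrees=True).as_matrix()
        a, b = plane_at(), plane_at(rot)
        assert classify_orientation(a, b) == classify_orientation(b, a)


class TestDetectStacks:
    def test_scripted_hexamer_and_tetramer(self):
        traj, _ = generate_scripted(stack_scenario([6, 4], n_frames=1))
        rec = detect_stacks(traj, 0)
        assert sorted(rec.sizes) == [4, 6]
        assert rec.singleton_ids == []

    def test_widely_separated_molecules_are_singletons(self):
        poses = [(I3, (40.0 * i, 0, 0)) for i in range(10)]
        rec = detect_stacks(traj_from_poses(poses), 0)
        assert rec.stacks == [] and len(rec.singleton_ids) == 10

    def test_trimer_with_alternating_orientations(self):
        traj, _ = generate_scripted(
            stack_scenario([3], n_frames=1, alternating=True)
        )
        rec = detect_stacks(traj, 0)
        assert len(rec.stacks) == 1
        st_ = rec.stacks[0]
        assert st_.member_ids == ["MB1", "MB2", "MB3"]
        assert st_.orientations == [ANTIPARALLEL, ANTIPARALLEL]
        assert st_.mean_spacing == pytest.approx(3.7, abs=1e-6)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_components(self, seed):
        """Connected components equal an independent O(n^2) union-find
        for random configurations of up to 6 molecules."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        poses = random_poses(rng, n, box=10.0)
        traj = traj_from_poses(poses)
        rec = detect_stacks(traj, 0)
        got = {frozenset(int(m[2:]) - 1 for m in st_.member_ids)
               for st_ in rec.stacks}
        got |= {frozenset([int(s[2:]) - 1]) for s in rec.singleton_ids}
        ring_sets = [traj.ring_coords(0, m) for m in traj.mb_ids]
        assert got == set(oracle_components(ring_sets))

    def test_partition_property(self):
        rng = np.random.default_rng(7)
        traj = traj_from_poses(random_poses(rng, 8, box=14.0))
        rec = detect_stacks(traj, 0)
        seen = [m for st_ in rec.stacks for m in st_.member_ids]
        seen += rec.singleton_ids
        assert sorted(seen) == sorted(traj.mb_ids)

    def test_invariant_under_global_rigid_motion(self):
        rng = np.random.default_rng(11)
        poses = random_poses(rng, 6, box=10.0)
        rot = Rotation.random(random_state=rng).as_matrix()
        shift = rng.uniform(-30, 30, 3)
        moved = [(rot @ r, rot @ t + shift) for r, t in poses]
        rec_a = detect_stacks(traj_from_poses(poses), 0)
        rec_b = detect_stacks(traj_from_poses(moved), 0)
        assert [s.member_ids for s in rec_a.stacks] == [
            s.member_ids for s in rec_b.stacks
        ]
        for sa, sb in zip(rec_a.stacks, rec_b.stacks):
            assert sa.mean_spacing == pytest.approx(sb.mean_spacing, abs=1e-6)
            assert sa.orientations == sb.orientations


class TestStackStatistics:
    def test_constant_dimer_mean_spacing(self):
        traj, _ = generate_scripted(stack_scenario([2], n_frames=5))
        summary = stack_statistics(traj)
        assert summary.mean_spacing == pytest.approx(3.7, abs=1e-6)
        assert summary.mean_spacing_dimers == pytest.approx(3.7, abs=1e-6)

    def test_ten_mer_histogram_mass(self):
        traj, _ = generate_scripted(stack_scenario([10], n_frames=3))
        summary = stack_statistics(traj)
        assert summary.size_histogram == {10: 1.0}
        assert summary.modal_size == 10

    def test_empty_trajectory_rejected(self):
        traj, _ = generate_scripted(stack_scenario([2], n_frames=1))
        traj.coords = traj.coords[:0]
        with pytest.raises(ValueError):
            stack_statistics(traj)
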