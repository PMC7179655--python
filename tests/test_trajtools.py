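"""RMSD, B-factors, hydrogen bonds, centroid distances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import mmgbsa_ie as m
from mmgbsa_ie.errors import MMGBSAError
from mmgbsa_ie.trajtools import rmsd_matrix


def _random_cloud(rng, n=8):
    return rng.uniform(-5, 5, (n, 3))


class TestRmsd:
    def test_identical_zero(self, rng):
        x = _random_cloud(rng)
        assert m.rmsd(x, x) < 1e-12

    def test_rigid_transform_invariance(self, rng):
        x = _random_cloud(rng)
        rot = Rotation.from_euler("xyz", [0.4, 1.2, -0.9])
        y = rot.apply(x) + np.array([3.0, -2.0, 7.0])
        assert m.rmsd(y, x, superpose=True) == pytest.approx(0.0, abs=1e-8)
        # either input may move: symmetry of the superposed metric
        assert m.rmsd(x, y, superpose=True) == pytest.approx(0.0, abs=1e-8)

    def test_two_point_hand_calculation(self):
        a = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        b = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        a_c = a - a.mean(axis=0)
        b_c = b - b.mean(axis=0)
        assert m.rmsd(a_c, b_c, superpose=False) == pytest.approx(1.0)

    def test_too_few_atoms_for_superposition(self):
        with pytest.raises(MMGBSAError):
            m.rmsd(np.zeros((2, 3)), np.zeros((2, 3)), superpose=True)


class TestRmsdMatrix:
    def test_static_self_all_zero(self):
        coords = np.repeat(np.arange(12.0).reshape(1, 4, 3), 5, axis=0)
        traj = m.Trajectory.from_coords(coords)
        mat = rmsd_matrix(traj, traj)
        assert np.abs(mat).max() < 1e-8

    def test_self_diagonal_zero(self, rng):
        coords = rng.uniform(-3, 3, (4, 5, 3))
        traj = m.Trajectory.from_coords(coords)
        mat = rmsd_matrix(traj, traj)
        assert np.abs(np.diag(mat)).max() < 1e-8
        assert np.abs(mat - mat.T).max() < 1e-8

    def test_matches_per_cell_oracle(self, rng):
        a = m.Trajectory.from_coords(rng.uniform(-3, 3, (3, 6, 3)))
        b = m.Trajectory.from_coords(rng.uniform(-3, 3, (3, 6, 3)))
        mat = rmsd_matrix(a, b)
        for i in range(3):
            for j in range(3):
                assert mat[i, j] == pytest.approx(
                    m.rmsd(a.coords[i], b.coords[j]), abs=1e-10)


class TestBfactor:
    def test_static_zero(self):
        coords = np.repeat(np.arange(15.0).reshape(1, 5, 3), 4, axis=0)
        traj = m.Trajectory.from_coords(coords)
        assert np.abs(m.bfactor(traj)).max() < 1e-12

    def test_isotropic_jitter_analytic(self):
        """Gaussian jitter s per coordinate gives B = 8π²s²."""
        s = 0.5
        rng = np.random.default_rng(21)
        base = rng.uniform(-4, 4, (6, 3))
        coords = base[None] + rng.normal(0, s, (100_000, 6, 3))
        traj = m.Trajectory.from_coords(coords)
        b = m.bfactor(traj, align=False)
        assert np.abs(b / (8 * np.pi**2 * s**2) - 1).max() < 0.02

    def test_alignment_removes_rigid_drift(self):
        rng = np.random.default_rng(22)
        base = rng.uniform(-4, 4, (5, 3))
        drift = np.linspace(0, 10, 50)[:, None] * np.array([1.0, 0, 0])
        coords = base[None] + drift[:, None, :]
        traj = m.Trajectory.from_coords(coords)
        b = m.bfactor(traj, align=True)
        assert np.abs(b).max() < 1e-8

    def test_single_frame_rejected(self):
        traj = m.Trajectory.from_coords(np.zeros((1, 4, 3)))
        with pytest.raises(Exception):
            m.bfactor(traj)


class TestDetectHbonds:
    def _triad(self, distance, angle):
        from mmgbsa_ie.synth import _hbond_positions
        return _hbond_positions(distance, angle)

    @pytest.mark.parametrize("distance,angle,expected", [
        (3.4, 150.0, True),
        (3.6, 170.0, False),
        (3.4, 110.0, False),
        (3.5, 120.0, True),   # closed (inclusive) cutoffs at the boundary
    ])
    def test_geometric_criteria(self, distance, angle, expected):
        frame = self._triad(distance, angle)
        found = m.detect_hbonds(frame, donors=[(0, 1)], acceptors=[2])
        assert (len(found) == 1) == expected

    def test_donor_without_hydrogen(self):
        with pytest.raises(MMGBSAError):
            m.detect_hbonds(np.zeros((3, 3)), donors=[(0, None)], acceptors=[2])


class TestOccupancy:
    def test_planted_occupancy_recovered(self):
        traj, spec = m.planted_hbond_trajectory(50.0, 10_000, seed=13)
        rec = m.hbond_occupancy(traj, spec["donor"], spec["acceptor"])
        assert rec.occupancy == pytest.approx(50.0, abs=2.0)
        assert rec.occupancy == pytest.approx(100 * spec["bonded"].mean(),
                                              abs=1e-9)

    def test_always_and_never(self):
        always, spec = m.planted_hbond_trajectory(100.0, 200, seed=1)
        assert m.hbond_occupancy(always, spec["donor"],
                                 spec["acceptor"]).occupancy == 100.0
        never, spec2 = m.planted_hbond_trajectory(0.0, 200, seed=1)
        assert m.hbond_occupancy(never, spec2["donor"],
                                 spec2["acceptor"]).occupancy == 0.0

    def test_mean_geometry_over_all_frames(self):
        """Averages include broken frames, so the mean distance sits between
        the bonded (3.0 Å) and broken (4.5 Å) geometries."""
        traj, spec = m.planted_hbond_trajectory(50.0, 4000, seed=3)
        rec = m.hbond_occupancy(traj, spec["donor"], spec["acceptor"])
        assert 3.0 < rec.mean_distance < 4.5
        assert 100.0 < rec.mean_angle < 165.0

    def test_disjoint_events_add(self):
        """Occupancy of mutually exclusive bonded patterns is additive."""
        traj, spec = m.planted_hbond_trajectory(30.0, 5000, seed=5)
        bonded = spec["bonded"]
        occ = m.hbond_occupancy(traj, spec["donor"], spec["acceptor"]).occupancy
        assert occ == pytest.approx(100 * bonded.mean(), abs=1e-9)
        assert occ + (100 - occ) == pytest.approx(100.0)


class TestComDistance:
    def test_two_single_atoms(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 4.18
        traj = m.Trajectory.from_coords(coords)
        d = m.com_distance(traj, [0], [1])
        assert d[0] == pytest.approx(4.18)

    def test_translated_ring_pair(self):
        theta = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        ring = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(6)])
        other = ring + np.array([0.0, 0.0, 5.0])
        coords = np.concatenate([ring, other])[None]
        traj = m.Trajectory.from_coords(coords)
        d = m.com_distance(traj, list(range(6)), list(range(6, 12)))
        assert d[0] == pytest.approx(5.0, abs=1e-10)

    def test_straddling_group_centroid(self):
        coords = np.array([[[-1.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]]])
        traj = m.Trajectory.from_coords(coords)
        d = m.com_distance(traj, [0, 1], [2])
        assert d[0] == pytest.approx(3.0)

    def test_mass_weighting(self):
        coords = np.array([[[0.0, 0, 0], [2.0, 0, 0], [10.0, 0, 0]]])
        traj = m.Trajectory.from_coords(coords)
        masses = np.array([12.0, 1.0, 1.0])  # COM pulled toward atom 0
        d = m.com_distance(traj, [0, 1], [2], masses=masses)
        assert d[0] == pytest.approx(10.0 - 2.0 / 13.0)

    def test_zero_mass_rejected(self):
        traj = m.Trajectory.from_coords(np.zeros((1, 2, 3)))
        with pytest.raises(MMGBSAError):
            m.com_distance(traj, [0], [1], masses=np.zeros(2))
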