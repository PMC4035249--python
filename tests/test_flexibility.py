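"""Distance-fluctuation matrix and local flexibility against brute force."""

import numpy as np
import pytest

from dynafit.flexibility import (FluctuationMatrix, SigmoidFilter,
                                 difference_profile,
                                 distance_fluctuation_matrix,
                                 local_flexibility,
                                 windowed_local_flexibility)
from dynafit.synthetic_data import (FlexibilityRegimeSpec, build_topology,
                                    generate_flex_trajectory)
from dynafit.trajectory_io import ResidueProfile, Trajectory

from conftest import random_rotation_matrix


def brute_force_fluctuations(traj, frame_range=None):
    """Plain double loop over frames and residue pairs."""
    ca = traj.topology.ca_indices()
    coords = traj.slice_frames(frame_range)
    n = ca.size
    A = np.zeros((n, n))
    mean_d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = [float(np.linalg.norm(coords[t, ca[i]] - coords[t, ca[j]]))
                 for t in range(coords.shape[0])]
            d = np.asarray(d)
            mean_d[i, j] = d.mean()
            A[i, j] = np.mean(d**2) - d.mean() ** 2
    return A, mean_d


class TestFluctuationMatrix:
    def test_matches_brute_force(self, random_trajectory):
        fm = distance_fluctuation_matrix(random_trajectory)
        A_ref, d_ref = brute_force_fluctuations(random_trajectory)
        np.testing.assert_allclose(fm.A, A_ref, atol=1e-10)
        np.testing.assert_allclose(fm.mean_distance, d_ref, atol=1e-10)

    def test_rigid_motion_gives_zero_matrix(self, small_protein, rng):
        top, base = small_protein
        frames = []
        for _ in range(30):
            R = random_rotation_matrix(rng)
            t = rng.normal(size=3) * 20
            frames.append(base @ R.T + t)
        traj = Trajectory(top, np.stack(frames))
        fm = distance_fluctuation_matrix(traj)
        assert np.max(np.abs(fm.A)) < 1e-9

    def test_two_state_distance_has_unit_variance(self):
        # two residues alternating between 4 and 6 A separation: Var = 1
        top, base = build_topology(2, seed=0)
        frames = np.repeat(base[None], 10, axis=0)
        ca = top.ca_indices()
        for t in range(10):
            frames[t, 4:] = base[4:] + [(4.0 if t % 2 == 0 else 6.0)
                                        - (base[ca[1], 0] - base[ca[0], 0]), 0, 0]
        traj = Trajectory(top, frames)
        fm = distance_fluctuation_matrix(traj)
        assert fm.A[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert fm.mean_distance[0, 1] == pytest.approx(5.0, abs=1e-12)

    def test_duplicated_trajectory_leaves_matrix_unchanged(self, random_trajectory):
        fm1 = distance_fluctuation_matrix(random_trajectory)
        doubled = Trajectory(random_trajectory.topology,
                             np.concatenate([random_trajectory.coordinates] * 2))
        fm2 = distance_fluctuation_matrix(doubled)
        np.testing.assert_allclose(fm1.A, fm2.A, atol=1e-10)

    def test_displacement_scaling_scales_variance_quadratically(self):
        spec1 = FlexibilityRegimeSpec(5, [(10000, 0.2)], seed=42)
        spec2 = FlexibilityRegimeSpec(5, [(10000, 0.4)], seed=42)
        t1, _ = generate_flex_trajectory(spec1)
        t2, _ = generate_flex_trajectory(spec2)
        a1 = distance_fluctuation_matrix(t1).A
        a2 = distance_fluctuation_matrix(t2).A
        off = ~np.eye(5, dtype=bool)
        ratio = a2[off] / a1[off]
        assert np.all(np.abs(ratio - 4.0) < 0.6)  # alpha^2 within sampling error

    def test_monte_carlo_oracle_single_mobile_residue(self):
        # only residue 2 moves with sigma = 0.5: compare Var(d) to a large
        # Monte-Carlo estimate of Var(|r + eps|)
        sigma = 0.5
        spec = FlexibilityRegimeSpec(3, [(30000, [0.0, sigma, 0.0])], seed=9)
        traj, _ = generate_flex_trajectory(spec)
        fm = distance_fluctuation_matrix(traj)
        mc = np.random.default_rng(7)
        r = np.array([3.8, 0.0, 0.0])
        d = np.linalg.norm(r + sigma * mc.normal(size=(10**6, 3)), axis=1)
        var_ref = d.var()
        se = d.var() * np.sqrt(2.0 / 30000)  # sampling error of the pipeline value
        assert abs(fm.A[0, 1] - var_ref) < 3 * se + 3 * var_ref * np.sqrt(2 / 1e6)

    def test_too_few_frames_rejected(self, small_protein):
        top, base = small_protein
        traj = Trajectory(top, base[None])
        with pytest.raises(ValueError, match="2 frames"):
            distance_fluctuation_matrix(traj)


class TestSigmoid:
    def test_midpoint_is_half(self):
        f = SigmoidFilter()
        assert f(7.0) == pytest.approx(0.5)

    def test_strictly_decreasing_in_unit_interval(self):
        f = SigmoidFilter()
        d = np.linspace(0.1, 20, 200)
        vals = f(d)
        assert np.all(np.diff(vals) < 0)
        assert np.all((vals > 0) & (vals < 1))


class TestLocalFlexibility:
    def test_rigid_matrix_gives_zero_profile(self):
        n = 6
        A = FluctuationMatrix(np.zeros((n, n)),
                              np.abs(np.subtract.outer(range(n), range(n))) * 3.8,
                              (0, 10), np.arange(1, n + 1))
        p = local_flexibility(A)
        assert np.all(p.values == 0)

    def test_single_neighbor_at_midpoint_distance(self):
        # two residues at <d> = 7.0 with A = 2: p = f(7) * 2 = 1.0
        A = FluctuationMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]),
                              np.array([[0.0, 7.0], [7.0, 0.0]]),
                              (0, 10), np.array([1, 2]))
        p = local_flexibility(A)
        assert p.values[0] == pytest.approx(1.0)

    def test_matches_hand_unrolled_sum(self):
        n = 6
        rng = np.random.default_rng(3)
        mat = rng.random((n, n))
        mat = 0.5 * (mat + mat.T)
        np.fill_diagonal(mat, 0.0)
        dist = 3.0 + 2.0 * np.abs(np.subtract.outer(range(n), range(n))).astype(float)
        np.fill_diagonal(dist, 0.0)
        A = FluctuationMatrix(mat, dist, (0, 10), np.arange(1, n + 1))
        filt = SigmoidFilter()
        p = local_flexibility(A, filt)
        for i in range(n):
            expected = sum(filt(dist[i, j]) * mat[i, j]
                           for j in (i - 2, i - 1, i + 1, i + 2)
                           if 0 <= j < n)
            assert p.values[i] == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_global_rigid_motion(self, random_trajectory, rng):
        p0 = local_flexibility(distance_fluctuation_matrix(random_trajectory))
        R = random_rotation_matrix(rng)
        moved = Trajectory(random_trajectory.topology,
                           random_trajectory.coordinates @ R.T + [5.0, -3.0, 2.0])
        p1 = local_flexibility(distance_fluctuation_matrix(moved))
        np.testing.assert_allclose(p0.values, p1.values, atol=1e-9)


class TestWindowing:
    def test_window_ranges(self):
        spec = FlexibilityRegimeSpec(3, [(1000, 0.2)], seed=0)
        traj, _ = generate_flex_trajectory(spec)
        windows = windowed_local_flexibility(traj, 100)
        assert len(windows) == 10
        assert windows[0][0] == (0, 100)
        assert windows[-1][0] == (900, 1000)

    def test_whole_trajectory_is_not_mean_of_windows(self):
        # regime change: the union-range profile must be recomputed on all
        # frames, not averaged over window profiles
        spec = FlexibilityRegimeSpec(4, [(200, [0.1, 0.5, 0.1, 0.5]),
                                         (200, [0.5, 0.1, 0.5, 0.1])], seed=1)
        traj, _ = generate_flex_trajectory(spec)
        full = local_flexibility(distance_fluctuation_matrix(traj))
        windows = windowed_local_flexibility(traj, 200)
        mean_of_windows = np.mean([p.values for _, p in windows], axis=0)
        recomputed = local_flexibility(
            distance_fluctuation_matrix(traj, (0, traj.n_frames)))
        np.testing.assert_allclose(full.values, recomputed.values, atol=1e-12)
        assert not np.allclose(full.values, mean_of_windows, atol=1e-3)

    def test_zero_full_windows_rejected(self):
        spec = FlexibilityRegimeSpec(3, [(50, 0.2)], seed=0)
        traj, _ = generate_flex_trajectory(spec)
        with pytest.raises(ValueError, match="window"):
            windowed_local_flexibility(traj, 100)


class TestDifferenceProfile:
    def _profile(self, values, mask=None, label="p"):
        values = np.asarray(values, dtype=float)
        mask = np.ones(values.size, bool) if mask is None else np.asarray(mask)
        return ResidueProfile(np.arange(1, values.size + 1), values, mask, label)

    def test_identity_gives_zero(self):
        p = self._profile([1.0, 2.0, 3.0])
        diff = difference_profile(p, p)
        assert np.all(diff.values[diff.mask] == 0)

    def test_masks_are_intersected(self):
        holo = self._profile([1.0, 2.0, 3.0])
        apo = self._profile([1.0, 2.0, 3.0], mask=[True, False, True])
        diff = difference_profile(holo, apo)
        assert list(diff.mask) == [True, False, True]

    def test_constant_offset(self):
        apo = self._profile([1.0, 2.0, 3.0])
        holo = self._profile([1.5, 2.5, 3.5])
        diff = difference_profile(holo, apo)
        np.testing.assert_allclose(diff.values[diff.mask], 0.5)

    def test_disjoint_masks_rejected(self):
        holo = self._profile([1.0, 2.0], mask=[True, False])
        apo = self._profile([1.0, 2.0], mask=[False, True])
        with pytest.raises(ValueError, match="disjoint"):
            difference_profile(holo, apo)
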