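"""Seed determinism and planted ground truth of the synthetic generators."""

import numpy as np
import pytest
from scipy import stats

from dynafit.flexibility import distance_fluctuation_matrix
from dynafit.synthetic_data import (ConeVectorSpec, FlexibilityRegimeSpec,
                                    WaterKineticsSpec, analytic_cone_s2,
                                    build_topology, generate_cone_vectors,
                                    generate_experimental_profile,
                                    generate_flex_trajectory,
                                    generate_ligand_ensemble, generate_waters,
                                    generate_study_fixture)
from dynafit.trajectory_io import ResidueProfile


class TestDeterminism:
    def test_flex_trajectory_bit_identical(self):
        spec = FlexibilityRegimeSpec(4, [(50, 0.3)], seed=77)
        t1, _ = generate_flex_trajectory(spec)
        t2, _ = generate_flex_trajectory(FlexibilityRegimeSpec(4, [(50, 0.3)],
                                                               seed=77))
        np.testing.assert_array_equal(t1.coordinates, t2.coordinates)

    def test_cone_vectors_bit_identical(self):
        a, _ = generate_cone_vectors(ConeVectorSpec(8, 25.0, 100, seed=5))
        b, _ = generate_cone_vectors(ConeVectorSpec(8, 25.0, 100, seed=5))
        np.testing.assert_array_equal(a, b)

    def test_study_fixture_bit_identical(self):
        f1 = generate_study_fixture(seed=2, n_residues=10, n_windows=3,
                                    window_frames=30, planted_window_apo=1,
                                    planted_window_holo=2, with_waters=False)
        f2 = generate_study_fixture(seed=2, n_residues=10, n_windows=3,
                                    window_frames=30, planted_window_apo=1,
                                    planted_window_holo=2, with_waters=False)
        np.testing.assert_array_equal(f1.holo.coordinates, f2.holo.coordinates)
        np.testing.assert_array_equal(f1.exp_s2.values, f2.exp_s2.values)


class TestFlexGenerator:
    def test_zero_amplitude_gives_rigid_trajectory(self):
        spec = FlexibilityRegimeSpec(5, [(40, 0.0)], seed=1)
        traj, truths = generate_flex_trajectory(spec)
        fm = distance_fluctuation_matrix(traj)
        assert np.max(np.abs(fm.A)) < 1e-9
        assert np.all(truths[0].values == 0.0)

    def test_truth_profiles_echo_segment_amplitudes(self):
        amps = [0.1, 0.2, 0.3, 0.4]
        spec = FlexibilityRegimeSpec(4, [(10, amps), (10, 0.5)], seed=1)
        _, truths = generate_flex_trajectory(spec)
        np.testing.assert_allclose(truths[0].values, amps)
        np.testing.assert_allclose(truths[1].values, 0.5)


class TestConeGenerator:
    @pytest.mark.parametrize("angle,expected", [(0.0, 1.0), (180.0, 0.0)])
    def test_limits(self, angle, expected):
        _, s2 = generate_cone_vectors(ConeVectorSpec(5, angle, 10, seed=0))
        np.testing.assert_allclose(s2, expected)

    def test_zero_angle_vectors_are_static(self):
        V, _ = generate_cone_vectors(ConeVectorSpec(5, 0.0, 20, seed=3))
        assert np.max(np.abs(V - V[0])) < 1e-12

    def test_vectors_stay_inside_cone(self):
        spec = ConeVectorSpec(1, 30.0, 2000, seed=4)
        V, _ = generate_cone_vectors(spec)
        # the empirical mean direction approximates the cone axis
        axis = V[:, 0].mean(axis=0)
        axis /= np.linalg.norm(axis)
        cosines = V[:, 0] @ axis
        assert np.min(cosines) > np.cos(np.deg2rad(31.0))


class TestWaterGenerator:
    def test_mrt_truth_is_inverse_escape_rate(self):
        top, base = build_topology(3, n_waters=2)
        spec = WaterKineticsSpec(2, 0.1, n_frames=10)
        _, mrt = generate_waters(spec, top, base)
        np.testing.assert_allclose(mrt, 10.0)

    def test_unit_escape_rate_means_single_frame_visits(self):
        top, base = build_topology(3, n_waters=1)
        spec = WaterKineticsSpec(1, 1.0, k_return=1.0, n_frames=200, seed=1)
        coords, mrt = generate_waters(spec, top, base)
        assert mrt[0] == 1.0
        cb = base[top.atom_selection(residue=1, name="CB")[0]]
        d = np.linalg.norm(coords[:, 0, :] - cb, axis=1)
        in_shell = d < 3.5
        # alternates every frame: no two consecutive in-shell frames
        assert not np.any(in_shell[:-1] & in_shell[1:])

    def test_in_shell_positions_respect_cutoff_geometry(self):
        top, base = build_topology(4, n_waters=4)
        spec = WaterKineticsSpec(4, 0.2, n_frames=300, seed=6)
        coords, _ = generate_waters(spec, top, base)
        for w in range(4):
            cb = base[top.atom_selection(residue=w + 1, name="CB")[0]]
            d = np.linalg.norm(coords[:, w, :] - cb, axis=1)
            assert np.all((d < 3.5) | (d > 5.0))  # shell or bulk, never between


class TestLigandGenerator:
    def test_gaussian_spec_recovered_within_3_se(self):
        top, base = build_topology(6, n_ligand_atoms=3)
        lig, _ = generate_ligand_ensemble({3: (8.0, 0.5)}, top, base, 4000,
                                          seed=2)
        from dynafit.ligand_ensemble import sidechain_heavy_indices
        side = sidechain_heavy_indices(top, 3)
        com_side = base[side].mean(axis=0)
        com_lig = lig.mean(axis=1)
        d = np.linalg.norm(com_lig - com_side, axis=1)
        assert abs(d.mean() - 8.0) < 3 * 0.5 / np.sqrt(4000)

    def test_zero_sd_is_degenerate(self):
        top, base = build_topology(6, n_ligand_atoms=3)
        lig, _ = generate_ligand_ensemble({3: (8.0, 0.0)}, top, base, 50, seed=2)
        assert np.max(np.abs(lig - lig[0])) < 1e-12

    def test_disjoint_specs_give_disjoint_distance_supports(self):
        top, base = build_topology(6, n_ligand_atoms=3)
        near, _ = generate_ligand_ensemble({3: (6.0, 0.1)}, top, base, 500, seed=3)
        far, _ = generate_ligand_ensemble({3: (15.0, 0.1)}, top, base, 500, seed=3)
        from dynafit.ligand_ensemble import sidechain_heavy_indices
        com_side = base[sidechain_heavy_indices(top, 3)].mean(axis=0)
        d_near = np.linalg.norm(near.mean(axis=1) - com_side, axis=1)
        d_far = np.linalg.norm(far.mean(axis=1) - com_side, axis=1)
        assert d_near.max() < d_far.min()


class TestExperimentalProfiles:
    def _truth(self, n=40):
        rng = np.random.default_rng(0)
        return ResidueProfile(np.arange(1, n + 1), rng.random(n),
                              np.ones(n, bool), label="S2")

    def test_zero_noise_zero_mask_is_identity(self):
        truth = self._truth()
        out = generate_experimental_profile(truth, 0.0, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, truth.values)
        np.testing.assert_array_equal(out.mask, truth.mask)

    def test_mask_fraction_expectation(self):
        truth = self._truth(131)
        masked = [131 - generate_experimental_profile(truth, 0.0, 0.1,
                                                      seed=s).n_valid
                  for s in range(30)]
        assert 8 < np.mean(masked) < 18  # ~13 expected

    def test_correlation_decays_with_noise(self):
        truth = self._truth()
        mean_r = []
        for noise in (0.05, 0.3, 1.5):
            rs = []
            for s in range(50):
                out = generate_experimental_profile(truth, noise, 0.0, seed=s)
                rs.append(stats.pearsonr(truth.values, out.values).statistic)
            mean_r.append(np.mean(rs))
        assert mean_r[0] > mean_r[1] > mean_r[2]
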