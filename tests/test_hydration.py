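"""Shell occupancy, residence autocorrelation and MRT recovery."""

import numpy as np
import pytest

from dynafit.hydration import (ShellOccupancy, load_terminal_atom_table,
                               mrt_profile, mrt_ratio,
                               residence_autocorrelation, shell_occupancy,
                               shell_occupancy_bruteforce)
from dynafit.synthetic_data import (WaterKineticsSpec, build_topology,
                                    generate_waters)
from dynafit.trajectory_io import ResidueProfile, Trajectory


def _water_trajectory(n_residues, n_waters, water_coords, frame_spacing=10.0):
    top, base = build_topology(n_residues, n_waters=n_waters)
    n_frames = water_coords.shape[0]
    coords = np.repeat(base[None], n_frames, axis=0)
    wat_idx = top.atom_selection(component="water")
    coords[:, wat_idx, :] = water_coords
    return top, Trajectory(top, coords, frame_spacing)


class TestShellOccupancy:
    def test_water_inside_cutoff_always_assigned(self):
        top, base = build_topology(3, n_waters=1)
        cb = base[top.atom_selection(residue=2, name="CB")[0]]
        wat = np.repeat((cb + [0, 0, 3.0])[None, None, :], 10, axis=0)
        _, traj = _water_trajectory(3, 1, wat)
        occ = shell_occupancy(traj, 2)
        assert occ.indicator.all()

    def test_water_just_outside_cutoff_never_assigned(self):
        top, base = build_topology(3, n_waters=1)
        cb = base[top.atom_selection(residue=2, name="CB")[0]]
        wat = np.repeat((cb + [0, 0, 3.6])[None, None, :], 10, axis=0)
        _, traj = _water_trajectory(3, 1, wat)
        occ = shell_occupancy(traj, 2)
        assert not occ.indicator.any()

    def test_assignment_is_a_partition(self, rng):
        # a water is never in two residues' shells at once
        top, base = build_topology(4, n_waters=6)
        wat = base[top.atom_selection(component="protein")].mean(axis=0) \
            + 4.0 * rng.normal(size=(15, 6, 3))
        _, traj = _water_trajectory(4, 6, np.abs(wat))
        total = np.zeros((6, 15), dtype=int)
        for r in range(1, 5):
            total += shell_occupancy(traj, r).indicator.astype(int)
        assert total.max() <= 1

    def test_fast_path_equals_brute_force(self, rng):
        top, base = build_topology(5, n_waters=12)
        centre = base[top.atom_selection(component="protein")].mean(axis=0)
        wat = centre + rng.uniform(-8, 8, size=(20, 12, 3))
        _, traj = _water_trajectory(5, 12, wat)
        for r in (1, 3, 5):
            fast = shell_occupancy(traj, r).indicator
            slow = shell_occupancy_bruteforce(traj, r).indicator
            np.testing.assert_array_equal(fast, slow)

    def test_unknown_residue_name_rejected(self):
        top, base = build_topology(3, n_waters=1)
        names = np.array(top.residue_names, dtype=object)
        names[top.residue_index == 2] = "XXX"
        from dynafit.trajectory_io import Topology
        top2 = Topology(top.atom_names, top.elements, top.masses,
                        top.residue_index, names, top.components,
                        top.residue_labels, top.ligand_resnames,
                        top.water_resnames)
        traj = Trajectory(top2, np.repeat(base[None], 5, axis=0))
        with pytest.raises(ValueError, match="terminal"):
            shell_occupancy(traj, 2)

    def test_no_waters_is_an_error(self):
        top, base = build_topology(3)
        traj = Trajectory(top, np.repeat(base[None], 5, axis=0))
        with pytest.raises(ValueError, match="water"):
            shell_occupancy(traj, 1)


def _occ(indicator, dt=10.0):
    return ShellOccupancy(1, np.asarray(indicator, dtype=bool),
                          frame_spacing=dt)


class TestResidenceCurve:
    def test_permanent_occupancy_is_censored_at_trajectory_length(self):
        curve = residence_autocorrelation(_occ([[1] * 50]))
        assert np.allclose(curve.z, 1.0)
        assert curve.censored
        assert curve.mrt == pytest.approx(50 * 10.0)

    def test_alternating_occupancy_has_single_frame_mrt(self):
        curve = residence_autocorrelation(_occ([[1, 0] * 25]))
        assert curve.z[0] == 1.0
        assert curve.z[1] == 0.0
        assert curve.mrt == pytest.approx(10.0)  # one frame at 10 ps

    def test_hand_enumerated_short_series(self):
        # runs of lengths 3 and 2 in 10 frames: z(1) = (2+1)/(3+2 occupied
        # origins eligible) -- checked against direct enumeration
        ind = np.array([[1, 1, 1, 0, 0, 1, 1, 0, 0, 0]], dtype=bool)
        curve = residence_autocorrelation(_occ(ind), z_floor=0.0)
        T = 10
        for tau, z in zip(curve.lags, curve.z):
            origins = [t for t in range(T - tau) if ind[0, t]]
            surv = [t for t in origins if ind[0, t:t + tau + 1].all()]
            assert z == pytest.approx(len(surv) / len(origins))

    def test_survival_z_non_increasing(self, rng):
        ind = rng.random((5, 200)) < 0.4
        curve = residence_autocorrelation(_occ(ind), z_floor=0.0)
        assert np.all(np.diff(curve.z) <= 1e-12)

    def test_intermittent_dominates_survival(self, rng):
        ind = rng.random((5, 300)) < 0.5
        surv = residence_autocorrelation(_occ(ind), mode="survival",
                                         z_floor=0.0)
        inter = residence_autocorrelation(_occ(ind), mode="intermittent",
                                          z_floor=0.0)
        n = len(surv.z)
        assert np.all(inter.z[:n] - surv.z >= -1e-12)

    def test_never_occupied_flagged(self):
        curve = residence_autocorrelation(_occ([[0] * 20]))
        assert not curve.occupied
        assert curve.mrt == 0.0

    def test_markov_water_mrt_recovered(self):
        # desk-scale version of the kinetic recovery: 2e4 frames, 20 waters
        top, base = build_topology(5, n_waters=20)
        spec = WaterKineticsSpec(20, 0.1, n_frames=20000, seed=3)
        wat, truth = generate_waters(spec, top, base)
        _, traj = _water_trajectory(5, 20, wat)
        mrts = []
        for r in range(1, 6):
            occ = shell_occupancy(traj, r)
            curve = residence_autocorrelation(occ)
            mrts.append(curve.mrt / traj.frame_spacing)
        est = np.mean(mrts)
        assert abs(est - truth[0]) / truth[0] < 0.10


class TestMrtProfiles:
    def test_shared_kinetics_give_flat_profile(self):
        top, base = build_topology(4, n_waters=8)
        spec = WaterKineticsSpec(8, 0.2, n_frames=8000, seed=5)
        wat, _ = generate_waters(spec, top, base)
        _, traj = _water_trajectory(4, 8, wat)
        prof = mrt_profile(traj)
        vals = prof.valid_values()
        assert vals.size == 4
        assert np.max(np.abs(vals - vals.mean())) / vals.mean() < 0.25

    def test_planted_slow_residue_stands_out(self):
        top, base = build_topology(4, n_waters=8)
        k = np.full(8, 0.5)
        k[[0, 4]] = 0.05  # waters of residue 1 are 10x slower
        spec = WaterKineticsSpec(8, k, n_frames=8000, seed=6)
        wat, _ = generate_waters(spec, top, base)
        _, traj = _water_trajectory(4, 8, wat)
        prof = mrt_profile(traj)
        slow = prof.values[0]
        others = prof.values[1:4]
        assert np.all(slow > 5 * others)

    def test_ratio_identity_and_mask_propagation(self):
        idx = np.arange(1, 5)
        holo = ResidueProfile(idx, [2.0, 4.0, 6.0, 8.0],
                              [True, True, True, False], "MRT")
        apo = ResidueProfile(idx, [2.0, 2.0, 0.0, 8.0],
                             [True, False, True, True], "MRT")
        with pytest.warns(UserWarning, match="zero apo"):
            ratio = mrt_ratio(holo, apo)
        assert list(ratio.mask) == [True, False, False, False]
        assert ratio.values[0] == pytest.approx(1.0)

    def test_ratio_with_no_shared_residues_rejected(self):
        idx = np.arange(1, 4)
        holo = ResidueProfile(idx, [1.0, 1.0, 1.0], [True, False, False])
        apo = ResidueProfile(idx, [1.0, 1.0, 1.0], [False, True, True])
        with pytest.raises(ValueError, match="shared"):
            mrt_ratio(holo, apo)


def test_terminal_atom_table_contents():
    table = load_terminal_atom_table()
    assert table["LYS"] == ("NZ",)
    assert table["GLY"] == ("CA",)
    assert set(table["ASP"]) == {"OD1", "OD2"}
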