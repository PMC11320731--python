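"""Occupancy, density, hotspot-energy, H-bond, contact, RMSF/RMSD analyses."""

import numpy as np
import pandas as pd
import pytest

from probemap.core_io import BWMap, ParameterizedSystem, Trajectory
from probemap.mapping_analysis import (contact_frequency, density_grid,
                                       hydrogen_bonds, kabsch,
                                       pocket_occupancy, rank_hotspots,
                                       residue_interaction_energies,
                                       rmsd_series, rmsf, threshold_density)
from probemap.probe_sampler import NonbondedModel, pair_energy
from tests.conftest import make_atom


def two_body_system(probe_charge=0.2):
    """One center residue at origin plus one single-bead probe."""
    atoms = [make_atom(serial=1, resid=1, pos=(0, 0, 0), charge=-0.2),
             make_atom(serial=2, resid=2, pos=(20.0, 0, 0),
                       charge=probe_charge)]
    return ParameterizedSystem(atoms, [[1]])


class TestOccupancy:
    def test_handcrafted_five_frame_fixture(self):
        system = two_body_system()
        frames = np.zeros((5, 2, 3))
        near = [3.0, 0, 0]
        far = [15.0, 0, 0]
        for f, pos in enumerate([near, near, far, near, far]):
            frames[f, 1] = pos
        traj = Trajectory(system=system, frames=frames)
        res = pocket_occupancy(traj, center_residues=[("A", 1)], cutoff=4.0)
        assert res.percent_frames_occupied == pytest.approx(60.0)
        np.testing.assert_array_equal(res.per_frame_flags,
                                      [True, True, False, True, False])

    def test_probe_always_distant_gives_zero(self):
        system = two_body_system()
        frames = np.zeros((4, 2, 3))
        frames[:, 1, 0] = 12.0
        traj = Trajectory(system=system, frames=frames)
        res = pocket_occupancy(traj, center_residues=[("A", 1)], cutoff=4.0)
        assert res.percent_frames_occupied == 0.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        atoms = [make_atom(serial=i + 1, resid=(i // 3) + 1,
                           pos=rng.normal(scale=6, size=3))
                 for i in range(12)]
        probe_atoms = [make_atom(serial=13 + i, resid=10, chain="P",
                                 pos=rng.normal(scale=6, size=3))
                       for i in range(3)]
        system = ParameterizedSystem(atoms + probe_atoms, [[12, 13, 14]])
        frames = rng.normal(scale=6, size=(200, 15, 3))
        traj = Trajectory(system=system, frames=frames)
        centers = [("A", 1), ("A", 2)]
        res = pocket_occupancy(traj, center_residues=centers, cutoff=4.0)

        center_idx = [i for i in range(12) if atoms[i].residue_id in (1, 2)]
        expected = []
        for f in range(200):
            hit = False
            for p in (12, 13, 14):
                for c in center_idx:
                    if np.linalg.norm(frames[f, p] - frames[f, c]) <= 4.0:
                        hit = True
            expected.append(hit)
        np.testing.assert_array_equal(res.per_frame_flags, expected)
        assert res.percent_frames_occupied == pytest.approx(
            100.0 * np.mean(expected))

    def test_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        system = two_body_system()
        rng = np.random.default_rng(2)
        frames = rng.normal(scale=5, size=(30, 2, 3))
        traj = Trajectory(system=system, frames=frames)
        r1 = pocket_occupancy(traj, center_residues=[("A", 1)], cutoff=4.0)
        rot = Rotation.random(random_state=3)
        moved = rot.apply(frames.reshape(-1, 3)).reshape(frames.shape) + 7.5
        traj2 = Trajectory(system=system, frames=moved)
        r2 = pocket_occupancy(traj2, center_residues=[("A", 1)], cutoff=4.0)
        np.testing.assert_array_equal(r1.per_frame_flags, r2.per_frame_flags)

    def test_empty_probe_selection_rejected(self):
        system = two_body_system()
        traj = Trajectory(system=system, frames=np.zeros((2, 2, 3)))
        with pytest.raises(ValueError):
            pocket_occupancy(traj, probe_selection=np.array([], dtype=int),
                             center_residues=[("A", 1)])


class TestDensityGrid:
    def test_single_static_atom_binary_ball(self):
        system = ParameterizedSystem([make_atom(resid=1, pos=(0, 0, 0))], [[0]])
        traj = Trajectory(system=system, frames=np.zeros((1, 1, 3)))
        grid = density_grid(traj, spacing=1.0, radii={"C": 1.9})
        centers = grid.voxel_centers().reshape(-1, 3)
        vals = grid.values.ravel()
        d = np.linalg.norm(centers, axis=1)
        np.testing.assert_array_equal(vals[d <= 1.9], 1.0)
        np.testing.assert_array_equal(vals[d > 1.9], 0.0)

    def test_half_presence_gives_half(self):
        system = ParameterizedSystem([make_atom(resid=1, pos=(0, 0, 0))], [[0]])
        frames = np.zeros((2, 1, 3))
        frames[1, 0] = [30.0, 0, 0]
        traj = Trajectory(system=system, frames=frames)
        grid = density_grid(traj, spacing=1.0)
        assert grid.values.max() == pytest.approx(0.5)

    def test_matches_brute_force_rasterization(self):
        rng = np.random.default_rng(21)
        atoms = [make_atom(serial=i + 1, resid=1, chain="P",
                           element=["C", "N", "O"][i % 3],
                           pos=rng.normal(scale=3, size=3)) for i in range(4)]
        system = ParameterizedSystem(atoms, [list(range(4))])
        frames = rng.normal(scale=3, size=(50, 4, 3))
        traj = Trajectory(system=system, frames=frames)
        grid = density_grid(traj, spacing=1.0)
        radii = np.array([{"C": 1.7, "N": 1.55, "O": 1.52}[a.element]
                          for a in atoms])
        centers = grid.voxel_centers().reshape(-1, 3)
        counts = np.zeros(len(centers))
        for f in range(50):
            d = np.linalg.norm(centers[:, None] - frames[f][None], axis=-1)
            counts += (d <= radii[None]).any(axis=1)
        np.testing.assert_allclose(grid.values.ravel(), counts / 50,
                                   atol=1e-12)
        assert grid.values.min() >= 0.0 and grid.values.max() <= 1.0

    def test_refinement_never_loses_covered_atoms(self):
        rng = np.random.default_rng(22)
        atoms = [make_atom(serial=i + 1, resid=1, chain="P",
                           pos=rng.normal(scale=2, size=3)) for i in range(5)]
        system = ParameterizedSystem(atoms, [list(range(5))])
        frames = system.positions[None]
        traj = Trajectory(system=system, frames=frames)

        def covered(spacing):
            grid = density_grid(traj, spacing=spacing)
            thr = threshold_density(grid, 0.5)
            n = 0
            for a in atoms:
                if thr.count and np.min(np.linalg.norm(
                        thr.centers - a.position, axis=1)) <= a.vdw_radius:
                    n += 1
            return n

        assert covered(0.5) >= covered(1.0)

    def test_zero_extent_selection_rejected(self):
        system = two_body_system()
        traj = Trajectory(system=system, frames=np.zeros((2, 2, 3)))
        with pytest.raises(ValueError):
            density_grid(traj, selection=np.array([], dtype=int))


class TestThreshold:
    def _grid(self, values):
        from probemap.mapping_analysis import DensityGrid

        values = np.asarray(values, float)
        return DensityGrid(origin=np.zeros(3), spacing=1.0,
                           shape=values.shape, values=values)

    def test_all_zero_grid_empty(self):
        thr = threshold_density(self._grid(np.zeros((3, 3, 3))), 0.5)
        assert thr.count == 0
        assert thr.centroid is None

    def test_isovalue_zero_excludes_unvisited(self):
        v = np.zeros((2, 2, 2))
        v[0, 0, 0] = 0.3
        thr = threshold_density(self._grid(v), 0.0)
        assert thr.count == 1  # only the visited voxel

    def test_single_suprathreshold_voxel(self):
        v = np.zeros((4, 4, 4))
        v[1, 2, 3] = 0.6
        thr = threshold_density(self._grid(v), 0.5)
        np.testing.assert_array_equal(thr.indices, [[1, 2, 3]])
        np.testing.assert_allclose(thr.centers[0], [1.5, 2.5, 3.5])


class TestResidueEnergies:
    def _three_frame_fixture(self):
        atoms = [make_atom(serial=1, resid=1, pos=(0, 0, 0), charge=-0.3),
                 make_atom(serial=2, resid=1, pos=(1.5, 0, 0), charge=0.1),
                 make_atom(serial=3, resid=2, chain="P", pos=(4.0, 0, 0),
                           charge=0.25)]
        system = ParameterizedSystem(atoms, [[2]])
        frames = np.repeat(system.positions[None], 3, axis=0)
        return system, Trajectory(system=system, frames=frames)

    def test_static_frames_mean_equals_single_frame(self):
        system, traj = self._three_frame_fixture()
        model = NonbondedModel()
        table = residue_interaction_energies(traj, model=model, cutoff=5.0)
        assert len(table) == 1
        elec, vdw = pair_energy((system, system.residues[("A", 1)]),
                                (system, system.probes[0]), model)
        row = table.iloc[0]
        assert row.elec_mean == pytest.approx(elec, rel=1e-12)
        assert row.vdw_mean == pytest.approx(vdw, rel=1e-12)
        assert row.elec_sd == pytest.approx(0.0, abs=1e-12)
        assert row.n_frames == 3

    def test_probe_beyond_cutoff_gives_empty_table(self):
        system, traj = self._three_frame_fixture()
        frames = traj.frames.copy()
        frames[:, 2] = [40.0, 0, 0]
        table = residue_interaction_energies(
            Trajectory(system=system, frames=frames), cutoff=5.0)
        assert table.empty

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(31)
        atoms = []
        for i in range(40):  # 20 residues x 2 atoms
            atoms.append(make_atom(
                serial=i + 1, resid=i // 2 + 1, pos=rng.normal(scale=8, size=3),
                charge=rng.normal(scale=0.3), eps=0.1 + 0.1 * rng.random()))
        probe = [make_atom(serial=41, resid=99, chain="P",
                           pos=rng.normal(scale=8, size=3), charge=0.2)]
        system = ParameterizedSystem(atoms + probe, [[40]])
        frames = rng.normal(scale=8, size=(20, 41, 3))
        traj = Trajectory(system=system, frames=frames)
        model = NonbondedModel()
        table = residue_interaction_energies(traj, model=model, cutoff=5.0)

        expected = {}
        for f in range(20):
            for rid in range(1, 21):
                res_idx = [i for i in range(40) if atoms[i].residue_id == rid]
                dmin = min(np.linalg.norm(frames[f, i] - frames[f, 40])
                           for i in res_idx)
                if dmin > 5.0:
                    continue
                e = pair_energy((system, np.array(res_idx)),
                                (system, np.array([40])), model,
                                positions_a=frames[f, res_idx],
                                positions_b=frames[f, [40]])
                expected.setdefault(rid, []).append(e)
        assert set(table.residue_id) == set(expected)
        for rid, vals in expected.items():
            row = table[table.residue_id == rid].iloc[0]
            arr = np.array(vals)
            assert row.elec_mean == pytest.approx(arr[:, 0].mean(), rel=1e-9)
            assert row.vdw_mean == pytest.approx(arr[:, 1].mean(), rel=1e-9)
            assert row.n_frames == len(vals)

    def test_infinite_cutoff_additivity(self):
        rng = np.random.default_rng(32)
        atoms = []
        for i in range(30):
            atoms.append(make_atom(
                serial=i + 1, resid=i // 3 + 1, pos=rng.normal(scale=7, size=3),
                charge=rng.normal(scale=0.3)))
        probe = [make_atom(serial=31, resid=99, chain="P",
                           pos=(20.0, 0, 0), charge=0.3)]
        system = ParameterizedSystem(atoms + probe, [[30]])
        frames = rng.normal(scale=7, size=(5, 31, 3))
        traj = Trajectory(system=system, frames=frames)
        model = NonbondedModel(cutoff=1e6)
        table = residue_interaction_energies(traj, model=model, cutoff=np.inf)
        for f in range(5):
            tot = pair_energy((system, np.arange(30)),
                              (system, np.array([30])), model,
                              positions_a=frames[f, :30],
                              positions_b=frames[f, [30]])
            # per-frame sum over residues equals whole-receptor energy
            frame_sum = np.zeros(2)
            for rid in table.residue_id:
                res_idx = np.array([i for i in range(30)
                                    if atoms[i].residue_id == rid])
                frame_sum += pair_energy(
                    (system, res_idx), (system, np.array([30])), model,
                    positions_a=frames[f, res_idx],
                    positions_b=frames[f, [30]])
            assert frame_sum[0] == pytest.approx(tot[0], rel=1e-9)
            assert frame_sum[1] == pytest.approx(tot[1], rel=1e-9)
        # and the table means are consistent with the totals across frames
        total_mean = table.elec_mean.sum() + table.vdw_mean.sum()
        per_frame_totals = [sum(pair_energy(
            (system, np.arange(30)), (system, np.array([30])), model,
            positions_a=frames[f, :30], positions_b=frames[f, [30]]))
            for f in range(5)]
        assert total_mean == pytest.approx(np.mean(per_frame_totals), rel=1e-9)


class TestRanking:
    def _table(self, values):
        return pd.DataFrame([
            {"chain": "A", "residue_id": rid, "residue_name": "GLY",
             "bw": None, "elec_mean": v, "elec_sd": 0.0, "vdw_mean": 0.0,
             "vdw_sd": 0.0, "total_mean": v, "n_frames": 10}
            for rid, v in values])

    def test_most_negative_first(self):
        table = self._table([(1, -5.0), (2, -7.5), (3, 0.3)])
        ranked = rank_hotspots(table, key="electrostatic")
        assert list(ranked.residue_id) == [2, 1, 3]

    def test_ties_broken_by_residue_id(self):
        table = self._table([(9, -1.0), (3, -1.0), (5, -1.0)])
        ranked = rank_hotspots(table, key="total")
        assert list(ranked.residue_id) == [3, 5, 9]

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown ranking key"):
            rank_hotspots(self._table([(1, -1.0)]), key="bogus")

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            rank_hotspots(self._table([]))


class TestHydrogenBonds:
    def _system(self, acceptor_pos, h_pos):
        atoms = [make_atom(serial=1, name="OG", element="O", resid=1,
                           pos=(0, 0, 0)),
                 make_atom(serial=2, name="HG", element="H", resid=1,
                           pos=h_pos),
                 make_atom(serial=3, name="O", element="O", resid=2,
                           pos=acceptor_pos)]
        system = ParameterizedSystem(atoms)
        traj = Trajectory(system=system,
                          frames=system.positions[None])
        return traj

    def test_linear_bond_detected(self):
        traj = self._system(acceptor_pos=(2.8, 0, 0), h_pos=(1.0, 0, 0))
        out = hydrogen_bonds(traj, donors=[(0, 1)], acceptors=[2])
        assert out.iloc[0].fraction == 1.0

    def test_beyond_distance_cutoff_rejected(self):
        traj = self._system(acceptor_pos=(3.6, 0, 0), h_pos=(1.0, 0, 0))
        out = hydrogen_bonds(traj, donors=[(0, 1)], acceptors=[2])
        assert out.iloc[0].fraction == 0.0

    def test_angle_below_cutoff_rejected(self):
        # place the acceptor so the D-H...A angle is 85 degrees at D...A 2.8
        d_da = 2.8
        h = np.array([1.0, 0, 0])
        # D at origin, H on +x: the H->D direction is -x; place A on a ray
        # from H making 85 deg with H->D, at the t giving |D - A| = 2.8
        ang = np.radians(180.0 - 85.0)  # measured from +x
        direction = np.array([np.cos(ang), np.sin(ang), 0.0])
        b_coef = 2 * h @ direction
        c_coef = h @ h - d_da ** 2
        t = (-b_coef + np.sqrt(b_coef ** 2 - 4 * c_coef)) / 2
        acceptor = h + t * direction
        traj = self._system(acceptor_pos=acceptor, h_pos=h)
        out = hydrogen_bonds(traj, donors=[(0, 1)], acceptors=[2])
        assert np.linalg.norm(acceptor) == pytest.approx(2.8, abs=1e-9)
        assert out.iloc[0].fraction == 0.0

    def test_donor_without_hydrogen_rejected(self):
        traj = self._system(acceptor_pos=(2.8, 0, 0), h_pos=(1.0, 0, 0))
        with pytest.raises(ValueError, match="hydrogen"):
            hydrogen_bonds(traj, donors=[(0, None)], acceptors=[2])


class TestContacts:
    def _traj(self, separations):
        atoms = [make_atom(serial=1, resid=1, pos=(0, 0, 0)),
                 make_atom(serial=2, resid=2, pos=(0, 0, 0))]
        system = ParameterizedSystem(atoms)
        frames = np.zeros((len(separations), 2, 3))
        for f, s in enumerate(separations):
            frames[f, 1, 0] = s
        return Trajectory(system=system, frames=frames)

    def test_always_close_is_one(self):
        traj = self._traj([3.0] * 6)
        assert contact_frequency(traj, [0], [1], d_cut=4.0) == 1.0

    def test_always_far_is_zero(self):
        traj = self._traj([8.0] * 6)
        assert contact_frequency(traj, [0], [1], d_cut=4.0) == 0.0

    def test_mixed_ten_frames(self):
        traj = self._traj([3, 8, 3, 8, 3, 8, 3, 8, 8, 8.0])
        assert contact_frequency(traj, [0], [1], d_cut=4.0) == pytest.approx(0.4)

    def test_empty_group_rejected(self):
        traj = self._traj([3.0])
        with pytest.raises(ValueError):
            contact_frequency(traj, [], [1])

    def test_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        traj = self._traj([3, 8, 3, 5, 4.5])
        f1 = contact_frequency(traj, [0], [1], d_cut=4.0)
        rot = Rotation.random(random_state=8)
        moved = rot.apply(traj.frames.reshape(-1, 3)).reshape(traj.frames.shape)
        traj2 = Trajectory(system=traj.system, frames=moved + 3.3)
        assert contact_frequency(traj2, [0], [1], d_cut=4.0) == f1


class TestRMSFandRMSD:
    def test_static_trajectory_rmsf_zero(self):
        atoms = [make_atom(serial=i + 1, resid=i + 1,
                           pos=(float(i), 0, 0)) for i in range(4)]
        system = ParameterizedSystem(atoms)
        traj = Trajectory(system=system,
                          frames=np.repeat(system.positions[None], 5, axis=0))
        vals = rmsf(traj, per_residue=False)
        np.testing.assert_allclose(vals, 0.0, atol=1e-12)

    def test_two_point_alternation_closed_form(self):
        d = 1.25
        atoms = [make_atom(serial=1, resid=1, pos=(0, 0, 0))]
        system = ParameterizedSystem(atoms)
        frames = np.zeros((10, 1, 3))
        frames[::2, 0, 0] = d
        frames[1::2, 0, 0] = -d
        traj = Trajectory(system=system, frames=frames)
        vals = rmsf(traj, align=False, per_residue=False)
        assert vals[0] == pytest.approx(d, rel=1e-12)

    def test_rmsf_matches_two_pass_formula(self):
        rng = np.random.default_rng(41)
        atoms = [make_atom(serial=i + 1, resid=i + 1,
                           pos=rng.normal(size=3)) for i in range(6)]
        system = ParameterizedSystem(atoms)
        frames = rng.normal(scale=2, size=(25, 6, 3))
        traj = Trajectory(system=system, frames=frames)
        vals = rmsf(traj, align=False, per_residue=False)
        mean = frames.mean(axis=0)
        expected = np.sqrt(((frames - mean) ** 2).sum(axis=2).mean(axis=0))
        np.testing.assert_allclose(vals, expected, rtol=1e-12)

    def test_rmsd_identity_zero(self):
        rng = np.random.default_rng(42)
        atoms = [make_atom(serial=i + 1, resid=1, pos=rng.normal(size=3))
                 for i in range(5)]
        system = ParameterizedSystem(atoms)
        traj = Trajectory(system=system,
                          frames=np.repeat(system.positions[None], 3, axis=0))
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-12)

    def test_rigid_rotation_removed_by_superposition(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(43)
        base = rng.normal(scale=3, size=(7, 3))
        rot = Rotation.random(random_state=44)
        atoms = [make_atom(serial=i + 1, resid=1, pos=base[i])
                 for i in range(7)]
        system = ParameterizedSystem(atoms)
        frames = np.stack([base, rot.apply(base) + 2.0])
        traj = Trajectory(system=system, frames=frames)
        out = rmsd_series(traj, reference=0, superpose=True)
        assert out[1] == pytest.approx(0.0, abs=1e-9)

    def test_translation_without_superposition_pythagoras(self):
        base = np.zeros((3, 3))
        atoms = [make_atom(serial=i + 1, resid=1, pos=base[i])
                 for i in range(3)]
        system = ParameterizedSystem(atoms)
        frames = np.stack([base, base + np.array([3.0, 4.0, 0.0])])
        traj = Trajectory(system=system, frames=frames)
        out = rmsd_series(traj, reference=0, superpose=False)
        assert out[1] == pytest.approx(5.0, rel=1e-12)

    def test_kabsch_rejects_reflection(self):
        rng = np.random.default_rng(45)
        a = rng.normal(size=(6, 3))
        b = a.copy()
        b[:, 0] *= -1  # mirrored
        rot, _ = kabsch(b, a)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_single_frame_rmsf_rejected(self):
        atoms = [make_atom(serial=1, resid=1, pos=(0, 0, 0))]
        system = ParameterizedSystem(atoms)
        traj = Trajectory(system=system, frames=np.zeros((1, 1, 3)))
        with pytest.raises(ValueError):
            rmsf(traj)
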