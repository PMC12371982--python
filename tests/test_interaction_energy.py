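import numpy as np
import pandas as pd
import pytest

from knobdyn.domain_model import AtomSelection
from knobdyn.errors import ParameterAssignmentError
from knobdyn.interaction_energy import (
    EnergySeries,
    LJParameterSet,
    assign_lj_parameters,
    bonded_exclusion_pairs,
    classify_contacts,
    energy_series,
    find_local_minima,
    group_vdw_energy,
    infer_bonds,
    load_lj_table,
    summarize_energy,
)
from knobdyn.structure_io import Topology, Trajectory
from knobdyn.synthetic_data import generate_two_domain_lj_system

from _oracles import axis_angle_rotation, loop_lj_energy


def _sel(name, indices):
    return AtomSelection(domain_name=name, atom_subset="heavy", indices=np.array(indices))


def _uniform_params(n, rmin_half=1.908, eps=0.1094):
    return np.full(n, rmin_half), np.full(n, eps)


class TestAssignment:
    def test_generic_table_covers_toy_topology(self):
        topo, _, _ = generate_two_domain_lj_system(5, 5, 10.0, seed=1)
        rmin_half, eps = assign_lj_parameters(topo, load_lj_table("toy_lj"))
        np.testing.assert_allclose(rmin_half, 1.908)
        np.testing.assert_allclose(eps, 0.1094)

    def test_missing_entry_names_offender(self):
        table = LJParameterSet(
            rows=pd.DataFrame(
                [{"residue_name": "ALA", "atom_name": "CA", "type": "CX",
                  "r_min_half_A": 1.908, "epsilon_kcal": 0.1094}]
            )
        )
        topo = Topology(
            serial=np.array([1, 2]),
            atom_name=np.array(["CA", "OXT"]),
            element=np.array(["C", "O"]),
            res_id=np.array([1, 1]),
            ins_code=np.array(["", ""]),
            res_name=np.array(["ALA", "ALA"]),
            chain_id=np.array(["A", "A"]),
        )
        with pytest.raises(ParameterAssignmentError, match="OXT"):
            assign_lj_parameters(topo, table)

    def test_assignment_matches_bruteforce_lookup(self, small_system):
        topo = small_system["traj"].topology
        table = load_lj_table("ff14sb_lj")
        rmin_half, eps = assign_lj_parameters(topo, table)
        for i in range(0, topo.n_atoms, 37):  # spot-check a spread of atoms
            hit = table.lookup(str(topo.res_name[i]), str(topo.atom_name[i]))
            assert hit is not None
            assert rmin_half[i] == hit[0] and eps[i] == hit[1]

    def test_exact_rows_beat_wildcards(self):
        table = LJParameterSet(
            rows=pd.DataFrame(
                [
                    {"residue_name": "*", "atom_name": "*", "type": "GEN",
                     "r_min_half_A": 1.0, "epsilon_kcal": 0.1},
                    {"residue_name": "SER", "atom_name": "OG", "type": "OH",
                     "r_min_half_A": 1.721, "epsilon_kcal": 0.2104},
                ]
            )
        )
        assert table.lookup("SER", "OG")[0] == 1.721
        assert table.lookup("SER", "CB")[0] == 1.0


class TestGroupVdwEnergy:
    def test_pair_at_rmin_gives_minus_epsilon(self):
        rmin_half, eps_val = 1.908, 0.1094
        coords = np.array([[0.0, 0, 0], [2 * rmin_half, 0, 0]])
        rmh, eps = _uniform_params(2, rmin_half, eps_val)
        e = group_vdw_energy(coords, _sel("a", [0]), _sel("b", [1]), rmh, eps)
        assert e == pytest.approx(-eps_val, abs=1e-15)

    def test_beyond_cutoff_is_zero(self):
        coords = np.array([[0.0, 0, 0], [13.0, 0, 0]])
        rmh, eps = _uniform_params(2)
        assert group_vdw_energy(coords, _sel("a", [0]), _sel("b", [1]), rmh, eps,
                                cutoff=12.0) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        n = 50
        coords = np.vstack(
            [rng.uniform(0, 8, (25, 3)), rng.uniform(0, 8, (25, 3)) + [12.0, 0, 0]]
        )
        rmh = rng.uniform(1.4, 2.0, n)
        eps = rng.uniform(0.05, 0.25, n)
        ia, ib = list(range(25)), list(range(25, 50))
        e = group_vdw_energy(coords, _sel("a", ia), _sel("b", ib), rmh, eps, cutoff=12.0)
        oracle = loop_lj_energy(
            coords[ia], coords[ib], rmh[ia], rmh[ib], eps[ia], eps[ib], cutoff=12.0
        )
        assert e == pytest.approx(oracle, abs=1e-8)

    def test_symmetry_exact(self, rng):
        coords = np.vstack([rng.uniform(0, 6, (10, 3)),
                            rng.uniform(0, 6, (10, 3)) + [9.0, 0, 0]])
        rmh, eps = _uniform_params(20)
        a, b = _sel("a", range(10)), _sel("b", range(10, 20))
        assert group_vdw_energy(coords, a, b, rmh, eps) == group_vdw_energy(
            coords, b, a, rmh, eps
        )

    def test_rigid_transform_invariance(self, rng):
        coords = np.vstack([rng.uniform(0, 6, (10, 3)),
                            rng.uniform(0, 6, (10, 3)) + [9.0, 0, 0]])
        rmh, eps = _uniform_params(20)
        a, b = _sel("a", range(10)), _sel("b", range(10, 20))
        base = group_vdw_energy(coords, a, b, rmh, eps)
        rot = axis_angle_rotation([1, 1, 1], 123.0)
        moved = coords @ rot.T + np.array([5.0, -3.0, 2.0])
        assert abs(group_vdw_energy(moved, a, b, rmh, eps) - base) < 1e-9

    def test_tail_decays_monotonically_to_zero(self):
        rmh, eps = _uniform_params(2)
        rmin = 2 * rmh[0]
        energies = []
        for factor in np.linspace(1.0, 3.0, 15):
            coords = np.array([[0.0, 0, 0], [factor * rmin, 0, 0]])
            energies.append(
                group_vdw_energy(coords, _sel("a", [0]), _sel("b", [1]), rmh, eps,
                                 cutoff=1e9)
            )
        mags = np.abs(energies)
        assert all(m1 >= m2 for m1, m2 in zip(mags, mags[1:]))
        assert energies[0] == pytest.approx(-eps[0])

    def test_near_singular_pair_warns(self):
        coords = np.array([[0.0, 0, 0], [0.05, 0, 0]])
        rmh, eps = _uniform_params(2)
        with pytest.warns(UserWarning, match="near-singular"):
            group_vdw_energy(coords, _sel("a", [0]), _sel("b", [1]), rmh, eps)

    def test_bonded_exclusions_respected(self):
        # linear 5-atom chain, 1.5 A spacing: pairs within 3 bonds excluded
        coords = np.outer(np.arange(5.0), [1.5, 0, 0])
        topo = Topology(
            serial=np.arange(1, 6),
            atom_name=np.array(["C1"] * 5),
            element=np.array(["C"] * 5),
            res_id=np.arange(1, 6),
            ins_code=np.array([""] * 5),
            res_name=np.array(["LJT"] * 5),
            chain_id=np.array(["A"] * 5),
        )
        bonds = infer_bonds(coords, topo)
        assert set(bonds) == {(0, 1), (1, 2), (2, 3), (3, 4)}
        excl = bonded_exclusion_pairs(bonds, max_separation=3)
        assert excl == {(i, j) for i in range(5) for j in range(i + 1, 5) if j - i <= 3}
        rmh, eps = _uniform_params(5)
        e = group_vdw_energy(
            coords, _sel("a", [0, 1]), _sel("b", [2, 3, 4]), rmh, eps,
            exclusions=excl,
        )
        # only the 0-4 pair (4 bonds apart) survives
        r = 6.0
        q = (2 * rmh[0] / r) ** 6
        assert e == pytest.approx(eps[0] * (q * q - 2 * q), abs=1e-12)


class TestEnergySeries:
    def test_distant_groups_all_zero(self):
        frames = np.repeat(
            np.array([[[0.0, 0, 0], [40.0, 0, 0]]]), 4, axis=0
        )
        topo, _, _ = generate_two_domain_lj_system(1, 1, 40.0)
        traj = Trajectory(topology=topo, frames=frames, times=np.arange(4.0))
        rmh, eps = _uniform_params(2)
        s = energy_series(traj, _sel("a", [0]), _sel("b", [1]), rmh, eps)
        np.testing.assert_array_equal(s.e_vdw, 0.0)

    def test_per_frame_independence(self, rng):
        frames = rng.uniform(0, 10, (6, 10, 3))
        topo, _, _ = generate_two_domain_lj_system(5, 5, 5.0)
        rmh, eps = _uniform_params(10)
        a, b = _sel("a", range(5)), _sel("b", range(5, 10))
        traj = Trajectory(topology=topo, frames=frames, times=np.arange(6.0))
        s = energy_series(traj, a, b, rmh, eps)
        perm = np.array([3, 1, 5, 0, 2, 4])
        permuted = Trajectory(
            topology=topo, frames=frames[perm], times=np.arange(6.0)
        )
        s_perm = energy_series(permuted, a, b, rmh, eps)
        np.testing.assert_allclose(s_perm.e_vdw, s.e_vdw[perm])


class TestSummarizeEnergy:
    def test_constant_runs_average(self):
        runs = {
            lab: EnergySeries(lab, np.arange(3.0), np.full(3, val))
            for lab, val in zip("ABC", (-2.0, -4.0, -6.0))
        }
        out = summarize_energy(runs)
        assert out["Average"] == pytest.approx(-4.0)
        assert set(out) == {"A", "B", "C", "Average"}

    def test_equal_length_runs_match_concatenated_mean(self, rng):
        vals = {lab: rng.normal(-5, 2, 40) for lab in "AB"}
        runs = {
            lab: EnergySeries(lab, np.arange(40.0), v) for lab, v in vals.items()
        }
        out = summarize_energy(runs)
        assert out["Average"] == pytest.approx(
            np.concatenate(list(vals.values())).mean()
        )


class TestFindLocalMinima:
    def _series(self, values):
        values = np.asarray(values, dtype=float)
        return EnergySeries("x", np.arange(float(len(values))), values)

    def test_monotone_series_has_no_interior_minimum(self):
        assert find_local_minima(self._series(-np.arange(100.0)),
                                 smooth_window=5, min_separation=10) == []

    def test_v_shape_recovers_vertex(self):
        v = np.abs(np.arange(100.0) - 60.0)
        assert find_local_minima(self._series(v), smooth_window=1,
                                 min_separation=10) == [60]

    def test_two_planted_wells_recovered(self, rng):
        n = 500
        base = rng.normal(0, 0.05, n)
        for center, depth in ((120, 5.0), (370, 3.0)):
            x = np.arange(n)
            base -= depth * np.exp(-0.5 * ((x - center) / 15.0) ** 2)
        minima = find_local_minima(self._series(base), smooth_window=11,
                                   min_separation=60)
        assert len(minima) >= 2
        # deepest two straddle the planted centers, deepest first
        assert abs(minima[0] - 120) <= 11
        assert abs(minima[1] - 370) <= 11


class TestClassifyContacts:
    def _toy(self):
        # 5 knob-ish residues on chain A (one atom each), partner chain B
        coords = np.array(
            [
                [0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0], [30.0, 0, 0], [34.0, 0, 0],
                [0.0, 2.9, 0], [8.0, 4.2, 0], [60.0, 0, 0],
            ]
        )
        topo = Topology(
            serial=np.arange(1, 9),
            atom_name=np.array(["OD1", "CB", "CB", "CB", "CB", "ND2", "CB", "CB"]),
            element=np.array(["O", "C", "C", "C", "C", "N", "C", "C"]),
            res_id=np.array([1, 2, 3, 4, 5, 1, 2, 3]),
            ins_code=np.array([""] * 8),
            res_name=np.array(["ASP", "ALA", "ALA", "ALA", "ALA", "ASN", "ALA", "ALA"]),
            chain_id=np.array(list("AAAAABBB")),
        )
        return topo, coords

    def test_canonical_polar_and_nonpolar_classes(self):
        topo, coords = self._toy()
        report = classify_contacts(
            coords, topo, _sel("knob", range(5)), _sel("lc", range(5, 8))
        )
        classes = {
            (c.knob_residue[1], c.partner_residue[1]): c.contact_class
            for c in report.contacts
        }
        # Asp O at 2.9 A from Asn N: polar; carbon-carbon at 4.2 A: nonpolar
        assert classes[("1", "1")] == "polar"
        assert classes[("3", "2")] == "nonpolar"

    def test_distant_residues_absent(self):
        topo, coords = self._toy()
        report = classify_contacts(
            coords, topo, _sel("knob", range(5)), _sel("lc", range(5, 8))
        )
        partners = {(c.knob_residue[1], c.partner_residue[1]) for c in report.contacts}
        assert ("4", "3") not in partners and ("5", "3") not in partners

    def test_matches_distance_matrix_oracle(self):
        topo, coords = self._toy()
        report = classify_contacts(
            coords, topo, _sel("knob", range(5)), _sel("lc", range(5, 8)),
            contact_cutoff=4.5,
        )
        found = {(c.knob_residue, c.partner_residue) for c in report.contacts}
        oracle = set()
        for i in range(5):
            for j in range(5, 8):
                if np.linalg.norm(coords[i] - coords[j]) <= 4.5:
                    oracle.add(
                        ((str(topo.chain_id[i]), str(topo.res_id[i])),
                         (str(topo.chain_id[j]), str(topo.res_id[j])))
                    )
        assert found == oracle
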