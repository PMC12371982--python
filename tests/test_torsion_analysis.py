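import numpy as np
import pytest
from scipy.special import iv

from knobdyn.errors import DihedralUndefinedError
from knobdyn.structure_io import Trajectory
from knobdyn.synthetic_data import generate_torsion_process
from knobdyn.torsion_analysis import (
    TAFEntry,
    TAFProfile,
    TorsionSeries,
    circular_variance,
    compute_backbone_torsions,
    compute_taf,
    dihedral,
    flag_hinge_residues,
    ramachandran_evolution,
)

from _oracles import axis_angle_rotation, projection_dihedral


class TestDihedral:
    def test_planar_trans_is_180(self):
        # zigzag in a plane: p1 and p4 on opposite sides of the p2-p3 bond
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == pytest.approx(180.0)

    def test_planar_cis_is_0(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0)

    def test_sign_convention(self):
        # p4 rotated −60° (clockwise looking down the p2→p3 bond) from cis
        rot = axis_angle_rotation([1, 0, 0], -60.0)
        p4 = np.array([1, 0, 0]) + rot @ np.array([0, 1, 0])
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], p4) == pytest.approx(-60.0)

    def test_rotation_invariance(self, rng):
        quad = rng.uniform(-3, 3, size=(4, 3))
        base = dihedral(*quad)
        for _ in range(20):
            rot = axis_angle_rotation(rng.normal(size=3), rng.uniform(0, 360))
            shift = rng.normal(size=3)
            moved = quad @ rot.T + shift
            assert dihedral(*moved) == pytest.approx(base, abs=1e-9)

    def test_agrees_with_projection_oracle(self, rng):
        for _ in range(100):
            quad = rng.uniform(-3, 3, size=(4, 3))
            try:
                ours = dihedral(*quad)
            except DihedralUndefinedError:
                continue
            assert ours == pytest.approx(projection_dihedral(*quad), abs=1e-6)

    def test_collinear_points_rejected(self):
        with pytest.raises(DihedralUndefinedError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestBackboneTorsions:
    def test_strand_geometry_stable(self, small_system):
        traj = small_system["traj"]
        part = small_system["partition"]
        series = compute_backbone_torsions(traj, list(part.stalk_n)[1:-1])
        for s in series:
            # generator builds stalk strands at (phi, psi) = (-135, 135);
            # residues before the hinge never move
            if s.residue == small_system["truth"].flexible_residues[0]:
                continue
            assert np.allclose(s.phi, s.phi[0])
            assert np.allclose(s.psi, s.psi[0])

    def test_chain_boundaries_undefined(self, small_system):
        traj = small_system["traj"]
        topo = traj.topology
        first = ("H", topo.chain_residues("H")[0])
        last = ("H", topo.chain_residues("H")[-1])
        s_first, s_last = compute_backbone_torsions(traj, [first, last])
        assert s_first.phi is None and s_first.psi is not None
        assert s_last.psi is None and s_last.phi is not None

    def test_frame_independence_under_global_rigid_motion(self, small_system):
        traj = small_system["traj"]
        part = small_system["partition"]
        rot = axis_angle_rotation([1, 2, 3], 71.0)
        moved = Trajectory(
            topology=traj.topology,
            frames=traj.frames @ rot.T + np.array([4.0, -2.0, 9.0]),
            times=traj.times,
        )
        residues = list(part.stalk)
        for s0, s1 in zip(
            compute_backbone_torsions(traj, residues),
            compute_backbone_torsions(moved, residues),
        ):
            for a0, a1 in ((s0.phi, s1.phi), (s0.psi, s1.psi)):
                assert (a0 is None) == (a1 is None)
                if a0 is not None:
                    np.testing.assert_allclose(a0, a1, atol=1e-6)

    def test_hinge_psi_tracks_schedule(self, small_system):
        # the generator's hinge rotation changes exactly the hinge psi,
        # by exactly the scheduled angle
        traj = small_system["traj"]
        truth = small_system["truth"]
        (series,) = compute_backbone_torsions(traj, list(truth.flexible_residues))
        delta = np.abs(series.psi - series.psi[0])
        delta = np.minimum(delta, 360.0 - delta)
        applied = np.abs(truth.rotation_deg - truth.rotation_deg[0])
        np.testing.assert_allclose(delta, applied, atol=1e-6)


class TestTAF:
    def test_constant_series_zero(self):
        angles = generate_torsion_process(100, "constant", value=42.0)
        assert circular_variance(angles) == 0.0

    def test_antipodal_two_state_approaches_one(self):
        angles = generate_torsion_process(10000, "two_state", seed=3, delta=180.0)
        assert circular_variance(angles) >= 0.98

    @pytest.mark.parametrize("kappa", [8.0, 4.0, 2.0, 1.0])
    def test_von_mises_matches_bessel_ratio(self, kappa):
        angles = generate_torsion_process(10000, "von_mises", seed=9, kappa=kappa)
        expected = 1.0 - iv(1, kappa) / iv(0, kappa)
        assert circular_variance(angles) == pytest.approx(expected, abs=0.02)

    def test_monotone_in_dispersion(self):
        tafs = [
            circular_variance(generate_torsion_process(10000, "von_mises", seed=9, kappa=k))
            for k in (8.0, 4.0, 2.0, 1.0)
        ]
        assert all(a < b for a, b in zip(tafs, tafs[1:]))

    def test_invariant_under_rotation_and_wrapping(self, rng):
        angles = generate_torsion_process(500, "von_mises", seed=2, kappa=1.5)
        base = circular_variance(angles)
        shifted = np.mod(angles + 97.0 + 180.0, 360.0) - 180.0
        assert circular_variance(shifted) == pytest.approx(base, abs=1e-9)
        assert circular_variance(angles + 360.0) == pytest.approx(base, abs=1e-9)

    def test_bounds(self, rng):
        for seed in range(5):
            angles = generate_torsion_process(200, "von_mises", seed=seed, kappa=0.5)
            assert 0.0 <= circular_variance(angles) <= 1.0

    def test_undefined_angles_omitted_with_warning(self):
        series = TorsionSeries(residue=("H", "1"), times=np.arange(3.0), phi=None, psi=None)
        with pytest.warns(UserWarning, match="omitted"):
            assert compute_taf(series) is None


class TestHingeFlags:
    def _profile(self, taf_psi):
        return TAFProfile(
            entries=[TAFEntry(residue=("H", "5"), taf_phi=0.01, taf_psi=taf_psi)]
        )

    def test_above_threshold_flagged(self):
        assert flag_hinge_residues(self._profile(0.65)) == [("H", "5")]

    def test_exactly_at_threshold_not_flagged(self):
        assert flag_hinge_residues(self._profile(0.6)) == []

    def test_designated_flexible_residue_is_the_only_flag(self, small_system):
        # the 40-degree sinusoid spreads psi over +-40 deg: TAF well below
        # 0.6 everywhere, so nothing should be flagged at the default
        traj = small_system["traj"]
        part = small_system["partition"]
        scope = list(part.stalk) + [part.knob[0], part.knob[-1]]
        entries = [
            e
            for s in compute_backbone_torsions(traj, scope)
            if (e := compute_taf(s)) is not None
        ]
        assert flag_hinge_residues(TAFProfile(entries=entries)) == []


class TestRamachandran:
    def test_output_length_bookkeeping(self, small_system):
        traj = small_system["traj"]
        part = small_system["partition"]
        (series,) = compute_backbone_torsions(traj, [part.stalk_n[1]])
        points = ramachandran_evolution(series)
        assert points.shape == (traj.n_frames, 3)
        np.testing.assert_array_equal(points[:, 0], traj.times)

    def test_two_state_flipping_gives_two_clusters(self, small_system):
        traj = small_system["traj"]
        truth = small_system["truth"]
        (series,) = compute_backbone_torsions(traj, list(truth.flexible_residues))
        points = ramachandran_evolution(series)
        # noiseless sinusoid: psi values trace the schedule exactly
        assert len(np.unique(np.round(points[:, 2], 3))) > 2

    def test_undefined_angle_gives_empty(self):
        series = TorsionSeries(residue=("H", "1"), times=np.arange(3.0), phi=None, psi=np.zeros(3))
        assert ramachandran_evolution(series).shape == (0, 3)
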