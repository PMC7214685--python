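import numpy as np
import pytest

from trisym import (
    AssemblyModel,
    Conformer,
    Ensemble,
    MembraneSlab,
    RegionSpan,
    classify_termini,
    ensemble_ring_stats,
    interface_residues,
    linker_bridge_feasible,
    membrane_violation,
    ring_compatibility,
    ring_distance,
    tilt_angle,
)
from trisym import fixtures as fx

from conftest import protomer_from_points, random_rigid_transform


def triangle_trimer(side=10.0, n_res=3):
    """Three short vertical chains whose residue rings are equilateral
    triangles of the given side length."""
    h = side / np.sqrt(3)  # circumradius
    protomers = []
    for k, cid in enumerate("ABC"):
        ang = np.radians(120 * k)
        base = np.array([h * np.cos(ang), h * np.sin(ang), 0.0])
        pts = base + np.outer(np.arange(n_res), [0, 0, 3.8])
        protomers.append(protomer_from_points(pts, chain_id=cid))
    return AssemblyModel(protomers)


class TestRingDistance:
    def test_equilateral_triangle(self):
        assert ring_distance(triangle_trimer(side=10.0), 2) == pytest.approx(10.0)

    def test_missing_residue_raises(self):
        with pytest.raises(KeyError):
            ring_distance(triangle_trimer(), 99)

    def test_invariant_under_rigid_motion(self):
        trimer = triangle_trimer(side=12.0)
        rng = np.random.default_rng(1)
        for _ in range(5):
            tr = random_rigid_transform(rng)
            moved = AssemblyModel(
                [p.with_coordinates(tr.apply) for p in trimer.protomers]
            )
            assert ring_distance(moved, 1) == pytest.approx(
                ring_distance(trimer, 1), abs=1e-9
            )

    def test_closed_form_on_parallel_bundle(self, bundle):
        # straight traces at radius r: every ring is r*sqrt(3)
        for num in (1, 10, 20):
            assert ring_distance(bundle, num) == pytest.approx(7.0 * np.sqrt(3),
                                                               abs=1e-6)


class TestEnsembleRingStats:
    def test_identical_conformers_have_zero_sd(self, bundle):
        ens = Ensemble([bundle.as_conformer(), bundle.as_conformer(),
                        bundle.as_conformer()])
        rs = ensemble_ring_stats(ens, 10)
        assert rs.sd == 0.0
        assert len(rs.per_conformer) == 3

    def test_mean_and_sd_match_numpy_oracle(self):
        sides = [9.0, 10.0, 11.5, 12.0]
        ens = Ensemble([triangle_trimer(side=s).as_conformer() for s in sides])
        rs = ensemble_ring_stats(ens, 2)
        np.testing.assert_allclose(rs.per_conformer, sides)
        assert rs.mean == pytest.approx(np.mean(sides))
        assert rs.sd == pytest.approx(np.std(sides, ddof=1))

    def test_single_conformer_warns(self, bundle):
        with pytest.warns(UserWarning, match="single-conformer"):
            rs = ensemble_ring_stats(Ensemble([bundle.as_conformer()]), 10)
        assert rs.sd == 0.0

    def test_flexible_termini_have_larger_sd_than_core(self):
        bundle = fx.make_c3_bundle(n_residues=21, ring_radius=7.0)
        ens = fx.make_noisy_ensemble(bundle, n_conformers=50, sigma_core=0.2,
                                     sigma_end=2.0, seed=42)
        nums = bundle.protomers[0].residue_numbers
        sd_core = ensemble_ring_stats(ens, int(nums[len(nums) // 2])).sd
        sd_nt = ensemble_ring_stats(ens, int(nums[0])).sd
        sd_ct = ensemble_ring_stats(ens, int(nums[-1])).sd
        assert sd_nt > sd_core
        assert sd_ct > sd_core


class TestClassifyTermini:
    def test_close_close(self):
        tc = classify_termini(triangle_trimer(side=18.0, n_res=5), 1, 5,
                              threshold=30.0)
        assert tc.label == "close Nt/close Ct"
        assert tc.nt_ring == pytest.approx(18.0)

    def test_remote_remote(self):
        tc = classify_termini(triangle_trimer(side=50.0, n_res=5), 1, 5,
                              threshold=30.0)
        assert tc.label == "remote Nt/remote Ct"

    def test_boundary_is_close(self):
        tc = classify_termini(triangle_trimer(side=30.0, n_res=5), 1, 5,
                              threshold=30.0)
        assert (tc.nt_label, tc.ct_label) == ("close", "close")

    def test_consistent_with_ring_distance(self):
        trimer = triangle_trimer(side=25.0, n_res=4)
        tc = classify_termini(trimer, 1, 4, threshold=30.0)
        assert tc.nt_ring == pytest.approx(ring_distance(trimer, 1))
        assert tc.ct_ring == pytest.approx(ring_distance(trimer, 4))


class TestInterfaceResidues:
    def test_separated_protomers_no_interface(self):
        spans = interface_residues(triangle_trimer(side=100.0), cutoff=8.0)
        assert spans == [[], [], []]

    def test_planted_contacts_found_exactly(self):
        # chains far apart except residues 5-7, bent inward to touch
        protomers = []
        for k, cid in enumerate("ABC"):
            ang = np.radians(120 * k)
            base = 20.0 * np.array([np.cos(ang), np.sin(ang), 0.0])
            pts = base + np.outer(np.arange(12), [0, 0, 3.8])
            pts[4:7] -= 0.85 * base  # residues 5,6,7 swing to near the axis
            protomers.append(protomer_from_points(pts, chain_id=cid))
        spans = interface_residues(AssemblyModel(protomers), cutoff=8.0)
        for chain_spans in spans:
            assert [(s.start, s.end) for s in chain_spans] == [(5, 7)]

    def test_pair_exactly_at_cutoff_included(self):
        a = protomer_from_points([[0, 0, 0], [0, 0, 3.8], [0, 0, 7.6]], "A")
        b = protomer_from_points([[8.0, 0, 0], [50, 0, 3.8], [50, 0, 7.6]], "B")
        spans = interface_residues(AssemblyModel([a, b]), cutoff=8.0)
        assert [(s.start, s.end) for s in spans[0]] == [(1, 1)]

    def test_single_residue_hole_merged(self):
        pts_a = np.outer(np.arange(9), [0, 0, 3.8])
        a = protomer_from_points(pts_a, "A")
        pts_b = pts_a + np.array([50.0, 0, 0])
        pts_b[[1, 2, 4, 5]] -= np.array([45.0, 0, 0])  # residues 2,3,5,6 near A
        b = protomer_from_points(pts_b, "B")
        spans = interface_residues(AssemblyModel([a, b]), cutoff=8.0)
        assert [(s.start, s.end) for s in spans[1]] == [(2, 6)]


class TestLinkerBridge:
    def test_boundary_exactly_feasible(self):
        v = linker_bridge_feasible(0, [0, 0, 0], [3.8, 0, 0], per_bond_span=3.8)
        assert v.feasible
        assert v.slack == pytest.approx(0.0)

    def test_three_residues_cannot_span_20A(self):
        v = linker_bridge_feasible(3, [0, 0, 0], [20.0, 0, 0], per_bond_span=3.8)
        assert not v.feasible
        assert v.max_span == pytest.approx(15.2)
        assert v.slack == pytest.approx(-4.8)

    def test_three_residues_easily_span_9A(self):
        assert linker_bridge_feasible(3, [0, 0, 0], [9.0, 0, 0]).feasible

    def test_feasibility_monotone_in_missing_count(self):
        anchors = ([0, 0, 0], [17.0, 0, 0])
        flags = [linker_bridge_feasible(n, *anchors).feasible for n in range(12)]
        assert flags == sorted(flags)  # once feasible, stays feasible

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            linker_bridge_feasible(-1, [0, 0, 0], [1, 0, 0])
        with pytest.raises(ValueError):
            linker_bridge_feasible(1, [0, 0, 0], [1, 0, 0], per_bond_span=0.0)


class TestRingCompatibility:
    @pytest.mark.parametrize(
        "a,b,tol,expected", [(18.0, 21.0, 5.0, True), (39.0, 21.0, 5.0, False)]
    )
    def test_known_verdicts(self, a, b, tol, expected):
        rc = ring_compatibility(a, b, tolerance=tol)
        assert rc.compatible is expected
        assert rc.mismatch == pytest.approx(abs(a - b))

    def test_equal_rings_always_compatible(self):
        rc = ring_compatibility(17.3, 17.3, tolerance=0.0)
        assert rc.compatible and rc.mismatch == 0.0


class TestTiltAngle:
    def test_axial_trace_along_normal(self):
        # zero-radius trace: the principal axis is exactly the helix axis
        trace = fx.make_ideal_helix(20, radius=0.0, tilt=0.0)
        assert tilt_angle(trace, MembraneSlab()) == pytest.approx(0.0, abs=1e-6)

    def test_axial_trace_in_membrane_plane(self):
        trace = fx.make_ideal_helix(20, radius=0.0, tilt=90.0)
        assert tilt_angle(trace, MembraneSlab()) == pytest.approx(90.0, abs=1e-6)

    @pytest.mark.parametrize("tilt", [10.0, 25.0, 45.0, 70.0])
    def test_known_tilt_recovered(self, tilt):
        helix = fx.make_ideal_helix(24, tilt=tilt, azimuth=33.0)
        assert tilt_angle(helix, MembraneSlab()) == pytest.approx(tilt, abs=1.0)

    def test_degenerate_inertia_suggests_termini_vector(self):
        from itertools import product

        cube = protomer_from_points(
            5.0 * np.array(list(product([-1.0, 1.0], repeat=3)))
        )  # isotropic inertia: no principal direction
        with pytest.raises(ValueError, match="termini_vector"):
            tilt_angle(cube, MembraneSlab(), axis_method="inertia")
        # the fallback method still returns something in range
        assert 0.0 <= tilt_angle(cube, MembraneSlab(),
                                 axis_method="termini_vector") <= 90.0

    def test_angle_folded_into_quadrant(self):
        helix = fx.make_ideal_helix(20, tilt=135.0)  # pointing "down"
        assert tilt_angle(helix, MembraneSlab()) == pytest.approx(45.0, abs=1.0)


class TestMembraneViolation:
    slab = MembraneSlab(outer_z=15.0, inner_z=-15.0)

    def test_everything_outside_slab(self):
        trimer = triangle_trimer(side=10.0, n_res=4)
        lifted = AssemblyModel([
            p.with_coordinates(lambda x: x + np.array([0, 0, 100.0]))
            for p in trimer.protomers
        ])
        assert membrane_violation(lifted, self.slab) == []

    def test_planted_intrusions_reported(self):
        pts = np.outer(np.arange(10), [0, 0, 6.0]) - np.array([0, 0, 25.0])
        # residues 2..5 have z in (-15, 15); the rest are outside
        a = protomer_from_points(pts, "A")
        b = protomer_from_points(pts + np.array([30.0, 0, 0]), "B")
        found = membrane_violation(AssemblyModel([a, b]), self.slab)
        # z = 6k - 25 lies strictly inside (-15, 15) for residues 3..7
        assert found == [("A", n) for n in range(3, 8)] + \
            [("B", n) for n in range(3, 8)]

    def test_allowed_span_whitelisted(self):
        pts = np.outer(np.arange(10), [0, 0, 6.0]) - np.array([0, 0, 25.0])
        a = protomer_from_points(pts, "A")
        b = protomer_from_points(pts + np.array([30.0, 0, 0]), "B")
        found = membrane_violation(
            AssemblyModel([a, b]), self.slab,
            allowed_spans=[RegionSpan(3, 7, "file")],
        )
        assert found == []
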