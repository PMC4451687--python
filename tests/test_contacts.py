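import numpy as np
import pytest

from nanocorona.contacts import (
    ContactConfig,
    contact_number,
    contact_probability,
    contact_series,
    contact_surface_area,
    sasa,
)
from nanocorona.structures import Frame, Trajectory, build_structure
from oracles import brute_contact_count, mc_sphere_sasa


def two_carbon_system(distance: float):
    s = build_structure(["C1", "C2"], ["GRA", "UNK"], [1, 2], ["G", "X"])
    frame = Frame(np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]))
    return s, frame


class TestContactNumber:
    @pytest.mark.parametrize("d,expected", [(6.5, 0), (5.9, 1), (6.0, 0)])
    def test_cutoff_boundary_is_strict(self, d, expected):
        s, frame = two_carbon_system(d)
        assert contact_number(frame, s, np.array([0]), np.array([1])) == expected

    def test_symmetric_in_selections(self, small_spec):
        from nanocorona.synthetic import generate

        traj, _ = generate(small_spec)
        s = traj.structure
        a, b = s.group_heavy_atoms("protein"), s.group_heavy_atoms("graphene")
        f = traj.frames[-1]
        assert contact_number(f, s, a, b) == contact_number(f, s, b, a)

    def test_invariant_under_rigid_motion(self, small_spec):
        from scipy.spatial.transform import Rotation

        from nanocorona.synthetic import generate

        traj, _ = generate(small_spec)
        s = traj.structure
        a, b = s.group_heavy_atoms("protein"), s.group_heavy_atoms("graphene")
        f = traj.frames[-1]
        rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.2]).as_matrix()
        moved = Frame(f.coordinates @ rot.T + np.array([5.0, -3.0, 8.0]))
        assert contact_number(moved, s, a, b) == contact_number(f, s, a, b)

    def test_overlapping_selections_rejected(self, small_spec):
        from nanocorona.synthetic import generate

        traj, _ = generate(small_spec)
        s = traj.structure
        a = s.group_heavy_atoms("protein")
        with pytest.raises(ValueError, match="disjoint"):
            contact_number(traj.frames[0], s, a, a)

    def test_equals_brute_force_on_fixture(self, small_spec):
        from nanocorona.synthetic import generate

        traj, _ = generate(small_spec)
        s = traj.structure
        a, b = s.group_heavy_atoms("protein"), s.group_heavy_atoms("graphene")
        for f in traj.frames[::10]:
            expected = brute_contact_count(f.coordinates[a], f.coordinates[b], 6.0)
            assert contact_number(f, s, a, b) == expected

    def test_minimum_image_convention_with_box(self):
        s = build_structure(["C1", "C2"], ["GRA", "UNK"], [1, 2], ["G", "X"])
        # 9.5 Å apart directly, but 0.5 Å through the periodic boundary
        frame = Frame(np.array([[0.25, 0.0, 0.0], [9.75, 0.0, 0.0]]), box=np.array([10.0, 50.0, 50.0]))
        assert contact_number(frame, s, np.array([0]), np.array([1]), ContactConfig(cutoff=1.0)) == 1


class TestContactSeries:
    def test_single_chain_equals_total(self, small_spec):
        from nanocorona.synthetic import generate

        traj, _ = generate(small_spec)
        cs = contact_series(traj, per_chain=True)
        assert list(cs.per_chain) == ["A"]
        assert np.array_equal(cs.per_chain["A"], cs.total)

    def test_chain_decomposition_sums_to_total(self):
        from nanocorona.synthetic import SyntheticSpec, generate

        traj, _ = generate(SyntheticSpec(n_frames=40))
        cs = contact_series(traj, per_chain=True)
        stacked = np.sum([v for v in cs.per_chain.values()], axis=0)
        assert np.array_equal(stacked, cs.total)

    def test_planted_two_stage_onsets_recovered(self):
        from nanocorona.synthetic import ChainPlan, SyntheticSpec, generate

        plan = [
            ChainPlan("A", ["ARG", "SER", "SER", "SER", "SER", "SER", "SER", "SER", "SER", "ARG"],
                      [True, False, False, False, False, False, False, False, False, True], 10),
            ChainPlan("B", ["TYR", "ASN", "ASN", "ASN", "ASN", "ASN", "ASN", "ASN", "ASN", "TYR"],
                      [True, False, False, False, False, False, False, False, False, True], 20),
        ]
        traj, _ = generate(SyntheticSpec(chains=plan, n_frames=30))
        cs = contact_series(traj, per_chain=True)
        for chain, onset in [("A", 10), ("B", 20)]:
            first = int(np.argmax(cs.per_chain[chain] > 0))
            assert first == onset


class TestContactProbability:
    def test_planted_six_of_ten_pattern(self):
        # one residue atom hops in and out of range on a scripted pattern
        s = build_structure(["CB", "C1"], ["ALA", "GRA"], [1, 2], ["A", "G"])
        pattern = [1, 1, 1, 1, 1, 1, 0, 0, 0, 0]  # 6 of 10 frames in contact
        frames = [
            Frame(np.array([[0.0, 0.0, 3.0 if hit else 30.0], [0.0, 0.0, 0.0]]))
            for hit in pattern
        ]
        prob = contact_probability(Trajectory(s, frames))
        assert prob.values[0, 0] == pytest.approx(0.6)

    def test_never_and_always(self, small_spec):
        from nanocorona.synthetic import generate

        traj, truth = generate(small_spec)
        prob = contact_probability(traj, window=(small_spec.chains[0].onset_frame, traj.n_frames))
        adsorbed = [k for k, i in enumerate(prob.residue_indices) if int(i) in truth.key_residues]
        background = [k for k, i in enumerate(prob.residue_indices) if int(i) not in truth.key_residues]
        assert np.allclose(prob.values[adsorbed, 0], 1.0)
        assert np.allclose(prob.values[background, 0], 0.0)

    def test_monotone_in_cutoff(self, small_spec):
        from nanocorona.synthetic import generate

        traj, _ = generate(small_spec)
        previous = None
        for cutoff in (4.0, 6.0, 8.0, 10.0):
            p = contact_probability(traj, cfg=ContactConfig(cutoff=cutoff)).values[:, 0]
            if previous is not None:
                assert np.all(p >= previous - 1e-12)
            previous = p

    def test_empty_window_rejected(self, small_spec):
        from nanocorona.synthetic import generate

        traj, _ = generate(small_spec)
        with pytest.raises(ValueError, match="window"):
            contact_probability(traj, window=(5, 5))


class TestSurfaceArea:
    def test_isolated_sphere_matches_analytic_area(self):
        cfg = ContactConfig()
        area = sasa(np.zeros((1, 3)), ["C"], cfg)
        expected = 4 * np.pi * (cfg.radii["C"] + cfg.probe_radius) ** 2
        assert area == pytest.approx(expected, rel=0.01)

    def test_separated_bodies_have_zero_contact_area(self):
        s = build_structure(["CB", "C1"], ["ALA", "GRA"], [1, 2], ["A", "G"])
        frame = Frame(np.array([[0.0, 0.0, 50.0], [0.0, 0.0, 0.0]]))
        area = contact_surface_area(frame, s, np.array([0]), np.array([1]))
        assert area == pytest.approx(0.0, abs=1e-9)

    def test_two_sphere_burial_matches_quadrature_oracle(self):
        cfg = ContactConfig()
        s = build_structure(["CB", "C1"], ["ALA", "GRA"], [1, 2], ["A", "G"])
        d = 3.0  # overlapping accessible shells
        frame = Frame(np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]))
        got = contact_surface_area(frame, s, np.array([0]), np.array([1]), cfg)
        centers = frame.coordinates
        radii = [cfg.radii["C"], cfg.radii["C"]]
        iso = [4 * np.pi * (r + cfg.probe_radius) ** 2 for r in radii]
        pair0 = mc_sphere_sasa(centers, radii, cfg.probe_radius, which=0, seed=1)
        pair1 = mc_sphere_sasa(centers, radii, cfg.probe_radius, which=1, seed=2)
        expected = 0.5 * (iso[0] + iso[1] - pair0 - pair1)
        assert got == pytest.approx(expected, rel=0.02)

    def test_missing_radius_is_a_configuration_error(self):
        with pytest.raises(KeyError, match="Se"):
            sasa(np.zeros((1, 3)), ["Se"], ContactConfig())

    def test_bounded_by_smaller_isolated_area(self):
        cfg = ContactConfig()
        s = build_structure(["CB", "C1"], ["ALA", "GRA"], [1, 2], ["A", "G"])
        frame = Frame(np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]))
        area = contact_surface_area(frame, s, np.array([0]), np.array([1]), cfg)
        iso = 4 * np.pi * (cfg.radii["C"] + cfg.probe_radius) ** 2
        assert 0.0 <= area <= iso
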