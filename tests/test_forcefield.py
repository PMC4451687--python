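import numpy as np
import pytest

from nanocorona.forcefield import (
    KJ_PER_KCAL,
    EnergyConfig,
    LJTable,
    adsorption_energy_drop,
    energy_series,
    lorentz_berthelot,
    pair_energy,
    residue_graphene_energy,
)
from nanocorona.graphene import GRAPHENE_LJ, LJParams, build_sheet, sheet_as_structure
from nanocorona.structures import Frame, Trajectory, build_structure
from oracles import brute_lj_energy, lj_direct


class TestPairEnergy:
    def test_minimum_is_minus_epsilon_at_rmin(self):
        p = LJParams(3.4, 0.3598)
        r_min = 2 ** (1 / 6) * 3.4
        assert pair_energy(r_min, p, p) == pytest.approx(-0.3598, rel=1e-12)

    def test_zero_crossing_at_sigma(self):
        p = LJParams(3.4, 0.3598)
        assert pair_energy(3.4, p, p) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_distance_rejected(self):
        p = LJParams(3.4, 0.3598)
        with pytest.raises(ValueError):
            pair_energy(0.0, p, p)

    def test_agrees_with_independent_direct_evaluation(self):
        cc = GRAPHENE_LJ
        prot_c = LJTable.default()["C"]
        for r in (3.0, 3.5, 4.2, 7.9):
            expected = lj_direct(r, prot_c.sigma, prot_c.epsilon, cc.sigma, cc.epsilon)
            assert pair_energy(r, prot_c, cc) == pytest.approx(expected, rel=1e-12)

    def test_tail_and_repulsive_wall_signs(self):
        p = LJParams(3.4, 0.3598)
        assert pair_energy(3.0, p, p) > 0
        assert pair_energy(5.0, p, p) < 0
        assert abs(pair_energy(50.0, p, p)) < 1e-6

    def test_lorentz_berthelot_combination(self):
        a, b = LJParams(3.0, 0.4), LJParams(4.0, 0.9)
        c = lorentz_berthelot(a, b)
        assert c.sigma == pytest.approx(3.5)
        assert c.epsilon == pytest.approx(0.6)


def one_atom_system(height: float):
    """Single carbon pseudo-residue above a one-cell sheet."""
    sheet_s, sheet_f = sheet_as_structure(build_sheet(3 * 1.42, np.sqrt(3) * 1.42))
    prot = build_structure(["CB"], ["ALA"], [1], ["A"])
    merged = prot.merged_with(sheet_s)
    centre = sheet_f.coordinates[:, :2].mean(axis=0)
    coords = np.vstack([[centre[0], centre[1], height], sheet_f.coordinates])
    return merged, Frame(coords)


class TestResidueGrapheneEnergy:
    def test_equals_brute_force_over_four_pair_sum(self):
        s, frame = one_atom_system(3.2)
        cfg = EnergyConfig(unit="kJ/mol")
        table = LJTable.default()
        got = residue_graphene_energy(frame, s, s.residues[0], s.group_heavy_atoms("graphene"), cfg, table)
        cross = lorentz_berthelot(table["C"], GRAPHENE_LJ)
        expected = brute_lj_energy(
            frame.coordinates[:1], frame.coordinates[1:], [cross.sigma], [cross.epsilon], cfg.cutoff
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_beyond_cutoff_is_zero(self):
        s, frame = one_atom_system(20.0)
        got = residue_graphene_energy(
            frame, s, s.residues[0], s.group_heavy_atoms("graphene"), EnergyConfig(), LJTable.default()
        )
        assert got == 0.0

    def test_translation_invariance(self):
        s, frame = one_atom_system(3.2)
        cfg = EnergyConfig()
        table = LJTable.default()
        sheet = s.group_heavy_atoms("graphene")
        e0 = residue_graphene_energy(frame, s, s.residues[0], sheet, cfg, table)
        shifted = Frame(frame.coordinates + np.array([11.0, -4.0, 2.5]))
        assert residue_graphene_energy(shifted, s, s.residues[0], sheet, cfg, table) == pytest.approx(e0, rel=1e-12)

    def test_unit_conversion(self):
        s, frame = one_atom_system(3.2)
        table = LJTable.default()
        sheet = s.group_heavy_atoms("graphene")
        kj = residue_graphene_energy(frame, s, s.residues[0], sheet, EnergyConfig(unit="kJ/mol"), table)
        kcal = residue_graphene_energy(frame, s, s.residues[0], sheet, EnergyConfig(unit="kcal/mol"), table)
        assert kj == pytest.approx(kcal * KJ_PER_KCAL, rel=1e-12)

    def test_missing_element_names_the_element(self):
        s, frame = one_atom_system(3.2)
        table = LJTable.from_text("C 0.355 0.35\n")  # graphene fine, but add a selenium residue
        prot = build_structure(["SE"], ["UNK"], [1], ["B"])
        merged = prot.merged_with(s)
        coords = np.vstack([[0.0, 0.0, 3.0], frame.coordinates])
        with pytest.raises(KeyError, match="Se"):
            residue_graphene_energy(
                Frame(coords), merged, merged.residues[0], merged.group_heavy_atoms("graphene"), EnergyConfig(), table
            )


class TestEnergySeries:
    def test_static_trajectory_gives_constant_series(self):
        s, frame = one_atom_system(3.5)
        traj = Trajectory(s, [Frame(frame.coordinates.copy()) for _ in range(4)])
        es = energy_series(traj, residues=[s.residues[0]], cfg=EnergyConfig())
        assert np.allclose(es.values, es.values[:, :1])

    def test_monotone_descent_gives_non_increasing_energy(self):
        # single atom over the sheet centre, separation shrinking toward r_min
        sheet_s, sheet_f = sheet_as_structure(build_sheet(6 * 1.42 * 3, 6 * np.sqrt(3) * 1.42))
        prot = build_structure(["CB"], ["ALA"], [1], ["A"])
        merged = prot.merged_with(sheet_s)
        centre_xy = sheet_f.coordinates[:, :2].mean(axis=0)
        frames = []
        for h in np.linspace(11.0, 4.0, 12):
            frames.append(Frame(np.vstack([[centre_xy[0], centre_xy[1], h], sheet_f.coordinates])))
        es = energy_series(Trajectory(merged, frames), residues=[merged.residues[0]], cfg=EnergyConfig())
        assert np.all(np.diff(es.values[0]) <= 1e-12)

    def test_equals_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        sheet_s, sheet_f = sheet_as_structure(build_sheet(12.0, 12.0))
        prot = build_structure(["CB", "OG", "NZ"], ["SER"] * 3, [1] * 3, ["A"] * 3)
        merged = prot.merged_with(sheet_s)
        table = LJTable.default()
        cfg = EnergyConfig(unit="kJ/mol", cutoff=9.0)
        frames = [
            Frame(np.vstack([rng.uniform(0, 10, (3, 3)) + [0, 0, 3.0], sheet_f.coordinates]))
            for _ in range(6)
        ]
        traj = Trajectory(merged, frames)
        es = energy_series(traj, residues=[merged.residues[0]], cfg=cfg, table=table)
        sheet_idx = merged.group_heavy_atoms("graphene")
        for fi, f in enumerate(frames):
            sig, eps = [], []
            for i in merged.residues[0].atom_indices:
                c = lorentz_berthelot(table[merged.atoms[i].element], GRAPHENE_LJ)
                sig.append(c.sigma)
                eps.append(c.epsilon)
            expected = brute_lj_energy(
                f.coordinates[merged.residues[0].atom_indices],
                f.coordinates[sheet_idx],
                sig,
                eps,
                cfg.cutoff,
            )
            assert es.values[0, fi] == pytest.approx(expected, abs=1e-9)

    def test_distant_sheet_extension_leaves_energy_unchanged(self):
        s, frame = one_atom_system(3.2)
        cfg = EnergyConfig()
        e0 = residue_graphene_energy(frame, s, s.residues[0], s.group_heavy_atoms("graphene"), cfg, LJTable.default())
        far_sheet, far_f = sheet_as_structure(build_sheet(10.0, 10.0, z=200.0))
        bigger = s.merged_with(far_sheet)
        coords = np.vstack([frame.coordinates, far_f.coordinates])
        e1 = residue_graphene_energy(
            Frame(coords), bigger, bigger.residues[0], bigger.group_heavy_atoms("graphene"), cfg, LJTable.default()
        )
        assert e1 == pytest.approx(e0, rel=1e-12)


class TestAdsorptionEnergyDrop:
    def test_constant_series_drops_zero(self):
        drops, mean, sd = adsorption_energy_drop([np.full(20, -3.0)], (0, 5), (10, 20))
        assert drops[0] == 0.0 and mean == 0.0

    def test_step_function_drop(self):
        row = np.concatenate([np.zeros(10), np.full(10, -10.0)])
        drops, mean, _ = adsorption_energy_drop([row], (0, 10), (10, 20))
        assert mean == pytest.approx(10.0)

    def test_three_replicas_closed_form_mean_sd(self):
        rows = [
            np.concatenate([np.zeros(5), np.full(5, -d)]) for d in (9.0, 10.0, 11.0)
        ]
        _, mean, sd = adsorption_energy_drop(rows, (0, 5), (5, 10))
        assert mean == pytest.approx(10.0)
        assert sd == pytest.approx(1.0)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            adsorption_energy_drop([np.zeros(10)], (0, 6), (5, 10))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            adsorption_energy_drop([np.zeros(10)], (3, 3), (5, 10))
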