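import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nanocorona.integrity import (
    NativeContactSet,
    build_native_contacts,
    q_fraction,
    q_series,
    rmsd,
    rmsd_series,
    superpose,
)
from nanocorona.structures import Frame, Structure, Trajectory, build_structure
from conftest import make_helix
from oracles import brute_native_pairs, quaternion_rmsd


def heavy_by_residue(s: Structure, frame: Frame):
    out = []
    for r in s.protein_residues():
        idx = [i for i in r.atom_indices if s.atoms[i].is_heavy]
        out.append(frame.coordinates[idx])
    return out


class TestBuildNativeContacts:
    def test_sequence_separation_rule_excludes_close_neighbours(self):
        # two adjacent residues 3 Å apart: excluded by j − i > 3
        names = ["CA"] * 6
        s = build_structure(names, ["ALA"] * 6, [1, 2, 3, 4, 5, 6], ["A"] * 6)
        coords = np.array([[i * 3.0, 0, 0] for i in range(6)], dtype=float)
        native = build_native_contacts(s, Frame(coords), cutoff=6.0)
        for i, j in native.pairs:
            assert j - i > 3

    def test_i_to_i_plus_4_within_cutoff_included(self):
        s = build_structure(["CA"] * 6, ["ALA"] * 6, list(range(1, 7)), ["A"] * 6)
        coords = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0], [5.9, 0, 0], [40, 0, 0]], dtype=float)
        native = build_native_contacts(s, Frame(coords), cutoff=6.0)
        assert (0, 4) in {tuple(p) for p in native.pairs}

    def test_matches_brute_force_all_pairs_scan(self, helix):
        s, frame = helix
        native = build_native_contacts(s, frame, cutoff=6.0)
        res_xyz = heavy_by_residue(s, frame)
        seq = [(r.chain_id, k) for k, r in enumerate(s.protein_residues())]
        expected = brute_native_pairs(res_xyz, seq, cutoff=6.0, min_sep=3)
        assert {tuple(p) for p in native.pairs} == expected

    def test_interchain_pairs_always_eligible(self):
        # same sequence positions on two chains, 5 Å apart: eligible despite j − i ≤ 3
        names, resnames, resids, chains, coords = [], [], [], [], []
        for c, z in [("A", 0.0), ("B", 5.0)]:
            for k in range(5):
                names.append("CA")
                resnames.append("GLY")
                resids.append(k + 1)
                chains.append(c)
                coords.append([k * 10.0, 0.0, z])
        s = build_structure(names, resnames, resids, chains)
        native = build_native_contacts(s, Frame(np.array(coords)), cutoff=6.0)
        pairs = {tuple(p) for p in native.pairs}
        assert (0, 5) in pairs  # chain A res 0 ↔ chain B res 0

    def test_too_few_residues_rejected(self, tripeptide):
        s, frame = tripeptide
        with pytest.raises(ValueError, match="few residues"):
            build_native_contacts(s, frame, min_separation=3)


class TestQFraction:
    def test_reference_against_its_own_native_set_is_one(self, helix):
        s, frame = helix
        native = build_native_contacts(s, frame, cutoff=6.0)
        assert native.n_pairs > 0
        assert q_fraction(frame, s, native) == 1.0

    def test_fully_unfolded_gives_zero(self, helix):
        s, frame = helix
        native = build_native_contacts(s, frame, cutoff=6.0)
        # pull every residue far apart along x
        coords = frame.coordinates.copy()
        for k, r in enumerate(s.protein_residues()):
            coords[r.atom_indices] += np.array([100.0 * k, 0.0, 0.0])
        assert q_fraction(Frame(coords), s, native) == 0.0

    def test_half_broken_native_set_gives_half(self, helix):
        s, frame = helix
        native = build_native_contacts(s, frame, cutoff=6.0)
        half = native.pairs[: native.n_pairs // 2]
        broken_res = set()
        coords = frame.coordinates.copy()
        # break exactly the first half of the pairs by exiling residue j of
        # each; restrict the set so no kept pair involves an exiled residue
        for i, j in half:
            broken_res.add(int(j))
        kept = [
            (i, j)
            for i, j in native.pairs
            if (int(i) in broken_res) == (int(j) in broken_res) or int(j) in broken_res
        ]
        sub = NativeContactSet(np.array([(i, j) for i, j in native.pairs if int(i) not in broken_res]), 6.0)
        survivors = [(i, j) for i, j in sub.pairs if int(j) not in broken_res]
        for k, r in enumerate(s.protein_residues()):
            if r.index in broken_res:
                coords[r.atom_indices] += np.array([0.0, 0.0, 500.0 + 10.0 * k])
        q = q_fraction(Frame(coords), s, sub)
        assert q == pytest.approx(len(survivors) / sub.n_pairs)

    def test_empty_native_set_is_an_error(self, helix):
        s, frame = helix
        with pytest.raises(ValueError, match="empty"):
            q_fraction(frame, s, NativeContactSet(np.empty((0, 2)), 6.0))

    def test_monotone_under_uniform_expansion(self, helix):
        s, frame = helix
        native = build_native_contacts(s, frame, cutoff=6.0)
        centre = frame.coordinates.mean(axis=0)
        previous = 1.0
        for factor in (1.0, 1.05, 1.15, 1.3, 1.6, 2.5):
            coords = centre + factor * (frame.coordinates - centre)
            q = q_fraction(Frame(coords), s, native)
            assert q <= previous + 1e-12
            previous = q

    def test_per_chain_q_in_unit_interval(self):
        from nanocorona.synthetic import SyntheticSpec, generate

        traj, _ = generate(SyntheticSpec(n_frames=40))
        native = build_native_contacts(traj.structure, traj.frames[0])
        qs = q_series(traj, native, per_chain=True)
        for col in qs.columns:
            if col.startswith("Q"):
                assert ((qs[col] >= 0) & (qs[col] <= 1)).all()


class TestRMSD:
    def test_identical_frames_give_zero(self, helix):
        s, frame = helix
        sel = s.group_heavy_atoms("protein")
        assert rmsd(frame, frame, sel) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance_with_superposition(self, helix):
        s, frame = helix
        sel = s.group_heavy_atoms("protein")
        rot = Rotation.from_euler("zyx", [0.7, -0.2, 1.9]).as_matrix()
        moved = Frame(frame.coordinates @ rot.T + np.array([3.0, -8.0, 12.0]))
        assert rmsd(moved, frame, sel, superpose_first=True) == pytest.approx(0.0, abs=1e-6)

    def test_matches_quaternion_method_on_toy_sets(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.normal(size=(4, 3)) * 3.0
            y = rng.normal(size=(4, 3)) * 3.0
            s = build_structure(["CA"] * 4, ["GLY"] * 4, [1, 2, 3, 4], ["A"] * 4)
            got = rmsd(Frame(x), Frame(y), np.arange(4), superpose_first=True)
            assert got == pytest.approx(quaternion_rmsd(x, y), abs=1e-6)

    def test_superposed_never_exceeds_raw(self, helix):
        s, frame = helix
        sel = s.group_heavy_atoms("protein")
        rng = np.random.default_rng(3)
        for _ in range(5):
            moved = Frame(frame.coordinates + rng.normal(scale=1.5, size=frame.coordinates.shape))
            with_fit = rmsd(moved, frame, sel, superpose_first=True)
            without = rmsd(moved, frame, sel, superpose_first=False)
            assert with_fit <= without + 1e-12

    def test_too_few_atoms_for_superposition(self, helix):
        s, frame = helix
        with pytest.raises(ValueError, match="3 atoms"):
            rmsd(frame, frame, np.array([0, 1]), superpose_first=True)

    def test_series_returns_per_chain_columns(self):
        from nanocorona.synthetic import SyntheticSpec, generate

        traj, _ = generate(SyntheticSpec(n_frames=40))
        df = rmsd_series(traj, traj.frames[0], per_chain=True)
        assert {"rmsd", "rmsd_A", "rmsd_B", "rmsd_C"} <= set(df.columns)
        # each chain only translates rigidly, so per-chain RMSD vanishes;
        # the whole-protein value need not (chains move on different schedules)
        for c in "ABC":
            assert np.allclose(df[f"rmsd_{c}"], 0.0, atol=1e-9)
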