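"""Synthetic protein + sheet + water trajectories with planted ground truth.

The generator emulates the qualitative features of protein-onto-graphene
adsorption trajectories so every pipeline stage can be tested without
external data:

* rigid hairpin-folded pseudo-protein chains (two antiparallel strands, so
  cross-strand native contacts exist and Q is well defined);
* a successive-wave approach schedule — each chain translates rigidly
  toward the sheet, crossing the 6 Å contact cutoff exactly at its planted
  onset frame and settling at an adsorbed gap where planted "adsorber"
  residues (flat Arg/Tyr/Trp-like side-chain templates) reach vdW energies
  well below −10 kcal/mol while elevated background residues stay out of
  range of both tagging rules;
* a static water-oxygen grid in a slab above the sheet whose interface
  layer under each adsorbing residue is expelled to a far reservoir at the
  chain's onset frame (scripted first-solvation-shell depletion);
* optional seeded Gaussian jitter, applied as an independent rigid
  displacement of each chain per frame (residues are rigid clusters and
  chains translate rigidly, so the noise respects that geometry),
  independent per replica.

Residue pseudo-geometries are fixed flat templates, not rotamers: every
metric downstream depends only on distances, so templates keep the planted
ground truth exact.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .graphene import build_sheet, sheet_as_structure
from .structures import Atom, Frame, Residue, Structure, Trajectory

__all__ = [
    "ChainPlan",
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "generate_replicas",
    "SIDECHAIN_TEMPLATES",
]


def _ring(n: int, radius: float) -> np.ndarray:
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)])


def _template(names: list[str], xy: np.ndarray) -> list[tuple[str, np.ndarray]]:
    return [(n, p) for n, p in zip(names, xy)]


#: flat side-chain heavy-atom templates (name, position); z = 0 plane lies
#: parallel to the sheet so adsorbed templates pave onto it
SIDECHAIN_TEMPLATES: dict[str, list[tuple[str, np.ndarray]]] = {
    # arginine-like: aliphatic stem + planar guanidinium (4 C, 3 N)
    "ARG": _template(
        ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
        np.vstack([_ring(6, 1.4), [[0.0, 0.0, 0.0]]])[[6, 0, 1, 2, 3, 4, 5]],
    ),
    # tyrosine-like: aromatic ring + centroid site + hydroxyl O (7 C, 1 O)
    "TYR": _template(
        ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
        np.vstack([[[0.0, 0.0, 0.0]], _ring(6, 1.39), [[2.1, 0.0, 0.0]]]),
    ),
    # tryptophan-like: fused-ring plate (7 C, 1 N)
    "TRP": _template(
        ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2"],
        np.vstack([[[0.0, 0.0, 0.0]], _ring(7, 1.6)]),
    ),
    # phenylalanine-like ring (7 C)
    "PHE": _template(
        ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
        np.vstack([[[0.0, 0.0, 0.0]], _ring(6, 1.39)]),
    ),
    # lysine-like short chain (4 C, 1 N)
    "LYS": _template(["CB", "CG", "CD", "CE", "NZ"], _ring(5, 1.5)),
    # compact background residues
    "SER": _template(["CB", "OG"], np.array([[0.0, 0.0, 0.0], [1.4, 0.0, 0.0]])),
    "ALA": _template(["CB"], np.zeros((1, 3))),
    "LEU": _template(["CB", "CG", "CD1", "CD2"], _ring(4, 1.3)),
    "ASN": _template(["CB", "CG", "OD1", "ND2"], _ring(4, 1.3)),
    "GLN": _template(["CB", "CG", "CD", "OE1", "NE2"], _ring(5, 1.4)),
    "GLU": _template(["CB", "CG", "CD", "OE1", "OE2"], _ring(5, 1.4)),
}


@dataclass
class ChainPlan:
    """One chain: residue names, which residues adsorb, and the onset frame.

    ``onset_frame=None`` means the chain never approaches the sheet.
    """

    chain_id: str
    residue_names: Sequence[str]
    adsorbing: Sequence[bool]
    onset_frame: Optional[int]

    def __post_init__(self) -> None:
        if len(self.residue_names) != len(self.adsorbing):
            raise ValueError("adsorbing flags must match residue count")
        for n in self.residue_names:
            if n not in SIDECHAIN_TEMPLATES:
                raise ValueError(f"no side-chain template for residue {n!r}")


@dataclass
class SyntheticSpec:
    """Full description of one synthetic adsorption experiment.

    Defaults encode the emulated study conditions: three chains adsorbing in
    successive waves (onsets 10/20/30), 100 frames sampled every 20 ps,
    adsorbed gap 3.6 Å (LJ contact distance), detached offset 8.4 Å (out of
    contact and essentially out of vdW range), approach step 2 Å/frame
    crossing the 6 Å cutoff exactly at the onset.
    """

    chains: list[ChainPlan] = field(default_factory=lambda: default_chain_plan())
    n_frames: int = 100
    time_step_ns: float = 0.02
    start_gap: float = 12.0
    contact_gap: float = 5.0  # gap at the onset frame, just inside the 6 Å cutoff
    final_gap: float = 3.45  # adsorbed height ≈ LJ contact-minimum distance
    approach_step: float = 2.0  # Å per frame
    detached_offset: float = 8.4  # elevation of non-adsorbing residues
    residue_spacing: float = 6.0  # along-strand centre spacing, Å
    strand_separation: float = 6.0  # hairpin strand gap, Å
    chain_spacing: float = 18.0  # between-chain y spacing, Å
    jitter: float = 0.0  # per-chain rigid-displacement Gaussian σ, Å
    water_spacing: float = 3.0
    water_slab: tuple[float, float] = (2.0, 14.0)  # z bounds of the grid, Å
    water_margin: float = 6.0  # xy margin of the grid around the chains
    water_clearance: float = 1.2  # carve-out radius around the solute path
    interface_radius: float = 4.0  # xy footprint for scripted expulsion
    interface_top: float = 5.2  # waters below this under a footprint are expelled
    sheet_margin: float = 14.0  # sheet border beyond the chain footprint
    seed: int = 0
    contact_cutoff: float = 6.0  # generator's own cutoff for planted counts

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.final_gap <= 0:
            raise ValueError("final gap must be positive")
        for c in self.chains:
            if c.onset_frame is not None and not (0 <= c.onset_frame < self.n_frames):
                raise ValueError(f"chain {c.chain_id}: onset frame outside [0, n_frames)")


def default_chain_plan() -> list[ChainPlan]:
    """Three hairpin chains, successive onsets, 14 planted adsorbers
    (9 basic + 5 aromatic) against polar/hydrophobic background.

    The adsorbing pattern of each chain is palindromic so that hairpin
    cross-strand partner residues share a flag; partner pairs then stay at a
    common height and supply the chain's native contacts.
    """
    return [
        ChainPlan(
            "A",
            ["ARG", "TYR", "SER", "ASN", "ARG", "ARG", "GLU", "LEU", "TRP", "ARG"],
            [True, True, False, False, True, True, False, False, True, True],
            onset_frame=10,
        ),
        ChainPlan(
            "B",
            ["ARG", "ASN", "TYR", "GLN", "SER", "GLU", "LEU", "ARG", "ASN", "ARG"],
            [True, False, True, False, False, False, False, True, False, True],
            onset_frame=20,
        ),
        ChainPlan(
            "C",
            ["ARG", "GLN", "TYR", "SER", "GLU", "ASN", "LEU", "TRP", "GLU", "ARG"],
            [True, False, True, False, False, False, False, True, False, True],
            onset_frame=30,
        ),
    ]


@dataclass
class GroundTruth:
    """Machine-readable planted truth, consistent with the emitted frames."""

    onset_frames: dict[int, Optional[int]]  # residue index → first contact frame
    chain_onsets: dict[str, Optional[int]]
    key_residues: set[int]
    contact_counts: dict[str, np.ndarray]  # chain → per-frame heavy-atom contacts
    total_contacts: np.ndarray
    fss_events: list[dict]  # {residue_index, frame, waters_removed}
    residue_names: dict[int, tuple[str, str]]  # index → (name, chain)

    def to_json(self) -> str:
        payload = {
            "onset_frames": {str(k): v for k, v in self.onset_frames.items()},
            "chain_onsets": self.chain_onsets,
            "key_residues": sorted(self.key_residues),
            "contact_counts": {c: v.tolist() for c, v in self.contact_counts.items()},
            "total_contacts": self.total_contacts.tolist(),
            "fss_events": self.fss_events,
            "residue_names": {str(k): list(v) for k, v in self.residue_names.items()},
        }
        return json.dumps(payload, indent=1)

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json())


def _chain_layout(spec: SyntheticSpec, plan: ChainPlan, y0: float):
    """Reference (pre-approach) template coordinates of one hairpin chain,
    expressed relative to the chain-bottom plane z = 0."""
    n = len(plan.residue_names)
    m = (n + 1) // 2
    centres = []
    for k in range(n):
        if k < m:
            x, y = k * spec.residue_spacing, y0
        else:
            x, y = (n - 1 - k) * spec.residue_spacing, y0 + spec.strand_separation
        z = 0.0 if plan.adsorbing[k] else spec.detached_offset
        centres.append(np.array([x, y, z]))
    atoms = []
    for k, name in enumerate(plan.residue_names):
        tpl = SIDECHAIN_TEMPLATES[name]
        coords = np.array([p for _, p in tpl]) + centres[k]
        names = [nm for nm, _ in tpl]
        atoms.append((names, coords))
    return atoms


def _gap(spec: SyntheticSpec, onset: Optional[int], frame: int) -> float:
    """Chain-bottom height above the sheet at a frame (scripted approach)."""
    if onset is None:
        return spec.start_gap
    g = spec.contact_gap + spec.approach_step * (onset - frame)
    return float(min(spec.start_gap, max(spec.final_gap, g)))


def generate(spec: SyntheticSpec, rng: Optional[np.random.Generator] = None) -> tuple[Trajectory, GroundTruth]:
    """Build the trajectory and its ground truth. Deterministic under a
    fixed spec/seed (``rng`` overrides the spec seed, for replicas)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    # ---- protein topology and per-chain reference geometry --------------
    names: list[str] = []
    resnames: list[str] = []
    chain_ids: list[str] = []
    rel_coords: list[np.ndarray] = []  # per atom, relative to chain bottom
    atom_chain: list[int] = []
    residue_of_atom: list[int] = []
    residue_names: dict[int, tuple[str, str]] = {}
    res_counter = 0
    for ci, plan in enumerate(spec.chains):
        y0 = ci * spec.chain_spacing
        for (anames, coords), rname in zip(_chain_layout(spec, plan, y0), plan.residue_names):
            for nm, p in zip(anames, coords):
                names.append(nm)
                resnames.append(rname)
                chain_ids.append(plan.chain_id)
                rel_coords.append(p)
                atom_chain.append(ci)
                residue_of_atom.append(res_counter)
            residue_names[res_counter] = (rname, plan.chain_id)
            res_counter += 1
    rel = np.array(rel_coords)
    atom_chain_arr = np.array(atom_chain)
    n_protein_atoms = rel.shape[0]
    n_protein_res = res_counter

    # ---- sheet ----------------------------------------------------------
    xy_min = rel[:, :2].min(axis=0) - spec.sheet_margin
    xy_max = rel[:, :2].max(axis=0) + spec.sheet_margin
    sheet = build_sheet(
        width=float(xy_max[0] - xy_min[0]),
        height=float(xy_max[1] - xy_min[1]),
        z=0.0,
    )
    sheet_xyz = sheet.carbon_coordinates + np.array([xy_min[0], xy_min[1], 0.0])

    # ---- water grid -----------------------------------------------------
    z0, z1 = spec.water_slab
    gx = np.arange(xy_min[0] + spec.water_margin, xy_max[0] - spec.water_margin, spec.water_spacing)
    gy = np.arange(xy_min[1] + spec.water_margin, xy_max[1] - spec.water_margin, spec.water_spacing)
    gz = np.arange(z0, z1 + 1e-9, spec.water_spacing)
    wx, wy, wz = np.meshgrid(gx, gy, gz, indexing="ij")
    waters0 = np.column_stack([wx.ravel(), wy.ravel(), wz.ravel()])
    n_waters = waters0.shape[0]
    reservoir_base = np.array([xy_min[0], xy_min[1], z1 + 60.0])
    reservoir = reservoir_base + np.column_stack(
        [
            spec.water_spacing * (np.arange(n_waters) % 64),
            spec.water_spacing * ((np.arange(n_waters) // 64) % 64),
            spec.water_spacing * (np.arange(n_waters) // 4096),
        ]
    )

    # protein coordinates for every frame (zero-jitter deterministic path)
    chain_gaps = np.array(
        [[_gap(spec, plan.onset_frame, f) for plan in spec.chains] for f in range(spec.n_frames)]
    )  # (frames, chains)
    base_frames = np.empty((spec.n_frames, n_protein_atoms, 3))
    for f in range(spec.n_frames):
        z_shift = chain_gaps[f][atom_chain_arr]
        base_frames[f] = rel + np.column_stack([np.zeros(n_protein_atoms), np.zeros(n_protein_atoms), z_shift])

    # carve out waters that the descending solute would ever overlap
    from scipy.spatial import cKDTree

    swept_min = np.full(n_waters, np.inf)
    for f in range(spec.n_frames):
        d, _ = cKDTree(base_frames[f]).query(waters0, k=1)
        swept_min = np.minimum(swept_min, d)
    carved = swept_min < spec.water_clearance

    # scripted interface expulsion: waters under an adsorbing residue's
    # footprint, below interface_top, leave at the chain's onset frame
    water_leave_frame = np.full(n_waters, -1, dtype=int)  # -1: never
    water_leave_frame[carved] = 0
    fss_events: list[dict] = []
    for ci, plan in enumerate(spec.chains):
        if plan.onset_frame is None:
            continue
        final_frame_idx = spec.n_frames - 1
        for r in range(n_protein_res):
            rname, rchain = residue_names[r]
            if rchain != plan.chain_id:
                continue
            k = r - min(i for i, (_, c) in residue_names.items() if c == plan.chain_id)
            if not plan.adsorbing[k]:
                continue
            mask = np.array([residue_of_atom[i] == r for i in range(n_protein_atoms)])
            final_xy = base_frames[final_frame_idx][mask][:, :2]
            dxy = np.linalg.norm(waters0[:, None, :2] - final_xy[None, :, :], axis=-1).min(axis=1)
            sel = (dxy <= spec.interface_radius) & (waters0[:, 2] <= spec.interface_top) & (water_leave_frame < 0)
            if sel.any():
                water_leave_frame[sel] = plan.onset_frame
                fss_events.append(
                    {
                        "residue_index": int(r),
                        "frame": int(plan.onset_frame),
                        "waters_removed": int(sel.sum()),
                    }
                )

    # ---- assemble topology ---------------------------------------------
    atoms: list[Atom] = []
    residues: list[Residue] = []
    serial = 1
    for i in range(n_protein_atoms):
        atoms.append(Atom(serial, names[i], _elem(names[i]), residue_of_atom[i]))
        serial += 1
    for r in range(n_protein_res):
        idx = np.array([i for i in range(n_protein_atoms) if residue_of_atom[i] == r], dtype=np.intp)
        rname, rchain = residue_names[r]
        residues.append(Residue(r, rname, rchain, idx, "protein"))
    sheet_res_index = n_protein_res
    n_sheet = sheet_xyz.shape[0]
    for i in range(n_sheet):
        atoms.append(Atom(serial, f"C{i + 1}", "C", sheet_res_index))
        serial += 1
    residues.append(
        Residue(sheet_res_index, "GRA", "G", np.arange(n_protein_atoms, n_protein_atoms + n_sheet, dtype=np.intp), "graphene")
    )
    w_start = n_protein_atoms + n_sheet
    for w in range(n_waters):
        ridx = sheet_res_index + 1 + w
        atoms.append(Atom(serial, "OW", "O", ridx))
        serial += 1
        residues.append(Residue(ridx, "HOH", "W", np.array([w_start + w], dtype=np.intp), "water"))
    structure = Structure(atoms, residues)

    # ---- frames ---------------------------------------------------------
    frames: list[Frame] = []
    for f in range(spec.n_frames):
        coords = np.empty((structure.n_atoms, 3))
        prot = base_frames[f].copy()
        if spec.jitter > 0:
            shifts = rng.normal(0.0, spec.jitter, size=(len(spec.chains), 3))
            prot += shifts[atom_chain_arr]
            # excluded volume of the rigid sheet: a chain cannot fluctuate
            # into the repulsive wall, so its lowest atom is floored just
            # below the equilibrium adsorption height
            floor = spec.final_gap - 0.1
            for ci in range(len(spec.chains)):
                mask = atom_chain_arr == ci
                zmin = prot[mask, 2].min()
                if zmin < floor:
                    prot[mask, 2] += floor - zmin
        coords[:n_protein_atoms] = prot
        coords[n_protein_atoms:w_start] = sheet_xyz
        leave_now = (water_leave_frame >= 0) & (water_leave_frame <= f)
        wpos = np.where(leave_now[:, None], reservoir, waters0)
        coords[w_start:] = wpos
        frames.append(Frame(coordinates=coords, time=f * spec.time_step_ns))
    traj = Trajectory(structure, frames)

    # ---- planted contact counts (generator's own brute force) -----------
    chain_counts = {plan.chain_id: np.zeros(spec.n_frames, dtype=int) for plan in spec.chains}
    onset_obs: dict[int, Optional[int]] = {}
    for r in range(n_protein_res):
        onset_obs[r] = None
    sheet_tree = cKDTree(sheet_xyz)
    for f in range(spec.n_frames):
        cand = sheet_tree.query_ball_point(base_frames[f], r=spec.contact_cutoff * (1 + 1e-12))
        per_atom = np.array(
            [
                int(
                    np.sum(
                        np.linalg.norm(sheet_xyz[js] - base_frames[f][i], axis=1) < spec.contact_cutoff
                    )
                )
                if js
                else 0
                for i, js in enumerate(cand)
            ]
        )
        for ci, plan in enumerate(spec.chains):
            chain_counts[plan.chain_id][f] = int(per_atom[atom_chain_arr == ci].sum())
        touched = {residue_of_atom[i] for i in np.nonzero(per_atom > 0)[0]}
        for r in touched:
            if onset_obs[r] is None:
                onset_obs[r] = f
    total = np.sum([v for v in chain_counts.values()], axis=0)
    key = {
        r
        for r in range(n_protein_res)
        if _is_adsorber(spec, residue_names[r][1], r, residue_names)
    }
    truth = GroundTruth(
        onset_frames=onset_obs,
        chain_onsets={p.chain_id: p.onset_frame for p in spec.chains},
        key_residues=key,
        contact_counts=chain_counts,
        total_contacts=total,
        fss_events=fss_events,
        residue_names=residue_names,
    )
    return traj, truth


def _is_adsorber(spec: SyntheticSpec, chain_id: str, r: int, residue_names: dict) -> bool:
    first = min(i for i, (_, c) in residue_names.items() if c == chain_id)
    plan = next(p for p in spec.chains if p.chain_id == chain_id)
    k = r - first
    return plan.onset_frame is not None and plan.adsorbing[k]


def _elem(atom_name: str) -> str:
    c = atom_name.strip()[0].upper()
    return c if c in "CNOSH" else "C"


def generate_replicas(
    spec: SyntheticSpec, n: int, seeds: Optional[Sequence[int]] = None
) -> tuple[list[Trajectory], GroundTruth]:
    """n trajectories sharing the schedule (hence one GroundTruth), with
    independent per-replica jitter streams."""
    if n < 1:
        raise ValueError("need at least one replica")
    if seeds is None:
        seeds = [spec.seed + k for k in range(n)]
    if len(seeds) != n or len(set(seeds)) != n:
        raise ValueError("seeds must be distinct and match the replica count")
    trajs = []
    truth = None
    for s in seeds:
        t, g = generate(spec, rng=np.random.default_rng(int(s)))
        trajs.append(t)
        if truth is None:
            truth = g
    return trajs, truth
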