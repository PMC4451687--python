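"""Structural-integrity metrics: fraction of native contacts Q and heavy-atom RMSD.

Two residues form a native contact when any heavy-atom pair across them is
closer than the cutoff (6.0 Å) in the reference (crystal) frame and the
residues are more than 3 apart in sequence (the separation rule applies
only within a chain; inter-chain pairs are always eligible). Q of a frame
is the fraction of native pairs whose minimum heavy-atom distance is still
below that cutoff; the reference itself has Q = 1 by construction. RMSD is
computed after optimal least-squares (Kabsch) superposition of the selected
heavy atoms, since without superposition rigid drift of an adsorbing
protein would swamp the internal deformation the metric is meant to track.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .neighbors import distance_matrix, pairs_within
from .structures import Frame, Structure, Trajectory

__all__ = [
    "NativeContactSet",
    "build_native_contacts",
    "q_fraction",
    "q_series",
    "superpose",
    "rmsd",
    "rmsd_series",
]


@dataclass
class NativeContactSet:
    """Deduplicated residue-index pairs (i < j) native in the reference."""

    pairs: np.ndarray  # (n, 2) residue indices, i < j
    cutoff: float
    min_separation: int = 3

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.intp).reshape(-1, 2)
        if self.pairs.size and np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ValueError("native-contact pairs must satisfy i < j")

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    def restricted_to_chain(self, structure: Structure, chain_id: str) -> "NativeContactSet":
        pos = {r.index for r in structure.residues if r.chain_id == chain_id}
        keep = [k for k, (i, j) in enumerate(self.pairs) if i in pos and j in pos]
        return NativeContactSet(self.pairs[keep], self.cutoff, self.min_separation)


def _protein_residue_heavy(structure: Structure):
    residues = structure.protein_residues()
    heavy = [
        np.asarray([i for i in r.atom_indices if structure.atoms[i].is_heavy], dtype=np.intp)
        for r in residues
    ]
    return residues, heavy


def build_native_contacts(
    structure: Structure,
    reference: Frame,
    cutoff: float = 6.0,
    min_separation: int = 3,
) -> NativeContactSet:
    """Scan the reference frame for native residue pairs.

    Accelerated by an atom-level neighbour query; equals the brute-force
    all-pairs scan (a tested contract).
    """
    residues, heavy = _protein_residue_heavy(structure)
    if len(residues) < min_separation + 2:
        raise ValueError("reference has too few residues for the separation rule")
    # sequence position within each chain, for the j − i rule
    seq_pos: dict[int, tuple[str, int]] = {}
    counters: dict[str, int] = {}
    for r in residues:
        k = counters.get(r.chain_id, 0)
        seq_pos[r.index] = (r.chain_id, k)
        counters[r.chain_id] = k + 1

    all_idx = np.concatenate([h for h in heavy if h.size])
    owner = np.concatenate([np.full(h.size, k, dtype=np.intp) for k, h in enumerate(heavy)])
    x = reference.coordinates[all_idx]
    ii, jj, _ = pairs_within(x, x, cutoff, reference.box, strict=True)
    found = set()
    for a, b in zip(owner[ii], owner[jj]):
        if a == b:
            continue
        i, j = (int(a), int(b)) if a < b else (int(b), int(a))
        ri, rj = residues[i].index, residues[j].index
        ci, pi = seq_pos[ri]
        cj, pj = seq_pos[rj]
        if ci == cj and abs(pj - pi) <= min_separation:
            continue
        found.add((ri, rj))
    pairs = np.array(sorted(found), dtype=np.intp).reshape(-1, 2)
    return NativeContactSet(pairs, cutoff, min_separation)


def q_fraction(frame: Frame, structure: Structure, native: NativeContactSet) -> float:
    """Fraction of native pairs still within the defining cutoff."""
    if native.n_pairs == 0:
        raise ValueError("native-contact set is empty; Q is undefined")
    residues, heavy = _protein_residue_heavy(structure)
    by_index = {r.index: heavy[k] for k, r in enumerate(residues)}
    kept = 0
    for i, j in native.pairs:
        d = distance_matrix(frame.coordinates[by_index[i]], frame.coordinates[by_index[j]], frame.box)
        if d.min() < native.cutoff:
            kept += 1
    return kept / native.n_pairs


def q_series(
    traj: Trajectory,
    native: NativeContactSet,
    per_chain: bool = False,
) -> pd.DataFrame:
    """Q per frame, optionally on chain-restricted native sets."""
    s = traj.structure
    cols = {"time_ns": traj.times()}
    cols["Q"] = np.array([q_fraction(f, s, native) for f in traj.frames])
    if per_chain:
        for c in [c for c in s.chains if any(r.group_label == "protein" and r.chain_id == c for r in s.residues)]:
            sub = native.restricted_to_chain(s, c)
            if sub.n_pairs == 0:
                continue
            cols[f"Q_{c}"] = np.array([q_fraction(f, s, sub) for f in traj.frames])
    return pd.DataFrame(cols)


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal least-squares rigid superposition (Kabsch, SVD) of mobile onto
    target; returns the transformed mobile coordinates."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("coordinate sets must have identical shape")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return mc @ rot.T + target.mean(axis=0)


def rmsd(
    frame: Frame,
    reference: Frame,
    atom_indices: np.ndarray,
    superpose_first: bool = True,
) -> float:
    """Root-mean-square deviation (Å) of the selected atoms."""
    idx = np.asarray(atom_indices, dtype=np.intp)
    x = frame.coordinates[idx]
    y = reference.coordinates[idx]
    if superpose_first:
        if idx.size < 3:
            raise ValueError("superposed RMSD needs at least 3 atoms")
        x = superpose(x, y)
    return float(np.sqrt(((x - y) ** 2).sum(axis=1).mean()))


def rmsd_series(
    traj: Trajectory,
    reference: Frame,
    per_chain: bool = False,
    superpose_first: bool = True,
    superpose_per_chain: bool = True,
) -> pd.DataFrame:
    """Heavy-atom RMSD to the reference per frame; per-chain columns
    superpose each chain independently by default."""
    s = traj.structure
    sel = s.group_heavy_atoms("protein")
    cols = {"time_ns": traj.times()}
    cols["rmsd"] = np.array([rmsd(f, reference, sel, superpose_first) for f in traj.frames])
    if per_chain:
        for c in s.chains:
            csel = s.chain_heavy_atoms(c)
            if csel.size < 3:
                continue
            if superpose_per_chain:
                cols[f"rmsd_{c}"] = np.array([rmsd(f, reference, csel, superpose_first) for f in traj.frames])
            else:
                # superpose on the whole protein, measure on the chain
                vals = []
                for f in traj.frames:
                    moved = superpose(f.coordinates[sel], reference.coordinates[sel]) if superpose_first else f.coordinates[sel]
                    lookup = {int(a): k for k, a in enumerate(sel)}
                    rows = np.array([lookup[int(a)] for a in csel])
                    dx = moved[rows] - reference.coordinates[csel]
                    vals.append(float(np.sqrt((dx ** 2).sum(axis=1).mean())))
                cols[f"rmsd_{c}"] = np.array(vals)
    return pd.DataFrame(cols)
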