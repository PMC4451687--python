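"""First-solvation-shell (FSS) water counting around side chains.

The FSS of a residue is the region within 5 Å of any heavy atom of its side
chain; the count is the number of distinct water molecules whose counting
site (the oxygen, by default) lies inside that region. Interface
dehydration on adsorption shows up as a drop in this count.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .neighbors import pairs_within
from .series import ResidueSeries
from .structures import Frame, Residue, Structure, Trajectory

__all__ = ["FSSConfig", "fss_count", "fss_series"]


@dataclass
class FSSConfig:
    shell_radius: float = 5.0  # Å
    water_site: str = "oxygen"  # 'oxygen' | 'any-atom'
    inclusive_boundary: bool = True  # 'within 5 Å' counts a water at exactly 5 Å

    def __post_init__(self) -> None:
        if self.shell_radius <= 0:
            raise ValueError("shell radius must be positive")
        if self.water_site not in {"oxygen", "any-atom"}:
            raise ValueError(f"unknown water_site rule {self.water_site!r}")


def _water_sites(structure: Structure, cfg: FSSConfig) -> tuple[np.ndarray, np.ndarray]:
    """Atom indices of water counting sites and the water (residue) each
    belongs to."""
    idx, owner = [], []
    for w, r in enumerate(structure.water_residues()):
        for i in r.atom_indices:
            a = structure.atoms[i]
            if cfg.water_site == "oxygen" and a.element != "O":
                continue
            if cfg.water_site == "any-atom" and not a.is_heavy:
                continue
            idx.append(i)
            owner.append(w)
    return np.asarray(idx, dtype=np.intp), np.asarray(owner, dtype=np.intp)


def fss_count(
    frame: Frame,
    structure: Structure,
    residue: Residue,
    cfg: Optional[FSSConfig] = None,
) -> int:
    """Number of distinct waters in the residue's side-chain FSS."""
    cfg = cfg or FSSConfig()
    side = residue.sidechain_atom_indices(structure)
    side = np.asarray([i for i in side if structure.atoms[i].is_heavy], dtype=np.intp)
    if side.size == 0:
        raise ValueError(
            f"residue {residue.name}-{residue.index} has no side-chain heavy atoms; "
            "use a backbone-shell variant for glycine"
        )
    sites, owner = _water_sites(structure, cfg)
    if sites.size == 0:
        return 0
    ii_w = _waters_in_shell(frame, side, sites, owner, cfg)
    return int(ii_w.size)


def _waters_in_shell(frame, side, sites, owner, cfg) -> np.ndarray:
    _, jj, _ = pairs_within(
        frame.coordinates[side],
        frame.coordinates[sites],
        cfg.shell_radius,
        frame.box,
        strict=not cfg.inclusive_boundary,
    )
    return np.unique(owner[jj])


def fss_series(
    traj: Trajectory,
    residues: Optional[Sequence[Residue]] = None,
    cfg: Optional[FSSConfig] = None,
) -> ResidueSeries:
    """Per-residue, per-frame FSS water counts (integers)."""
    cfg = cfg or FSSConfig()
    s = traj.structure
    if residues is None:
        residues = [
            r for r in s.protein_residues() if r.sidechain_atom_indices(s).size > 0
        ]
    sites, owner = _water_sites(s, cfg)
    values = np.zeros((len(residues), traj.n_frames), dtype=int)
    sides = []
    for r in residues:
        side = np.asarray(
            [i for i in r.sidechain_atom_indices(s) if s.atoms[i].is_heavy], dtype=np.intp
        )
        if side.size == 0:
            raise ValueError(f"residue {r.name}-{r.index} has no side-chain heavy atoms")
        sides.append(side)
    if sites.size:
        for fi, frame in enumerate(traj.frames):
            for k, side in enumerate(sides):
                values[k, fi] = _waters_in_shell(frame, side, sites, owner, cfg).size
    return ResidueSeries(
        residue_indices=np.array([r.index for r in residues]),
        frame_times=traj.times(),
        values=values,
        kind="fss",
        residue_labels=[f"{r.chain_id}:{r.name}-{r.index}" for r in residues],
    )
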