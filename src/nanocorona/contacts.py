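"""Heavy-atom contact metrics between protein and graphene sheet.

An atom–atom contact is a heavy-atom pair of the two groups strictly closer
than the cutoff (6.0 Å by default). Contact surface area is defined as half
the solvent-accessible surface area buried on complex formation,
(SASA_A + SASA_B − SASA_AB) / 2, with Shrake–Rupley SASA.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .neighbors import pairs_within
from .series import FrameSeries, ResidueSeries
from .structures import Frame, Residue, Structure, Trajectory

__all__ = [
    "ContactConfig",
    "VDW_RADII",
    "contact_number",
    "contact_series",
    "contact_probability",
    "contact_surface_area",
    "sasa",
]

#: van der Waals radii (Å) for the surface-area calculation
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}


@dataclass
class ContactConfig:
    cutoff: float = 6.0  # Å, strict '<'
    probe_radius: float = 1.4  # Å, water probe for SASA
    n_sphere_points: int = 960
    radii: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")
        if self.probe_radius < 0:
            raise ValueError("probe radius must be non-negative")


def contact_number(
    frame: Frame,
    structure: Structure,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cfg: Optional[ContactConfig] = None,
) -> int:
    """Count heavy-atom pairs (a ∈ A, b ∈ B) with distance < cutoff."""
    cfg = cfg or ContactConfig()
    group_a = np.asarray(group_a, dtype=np.intp)
    group_b = np.asarray(group_b, dtype=np.intp)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("contact selections must be disjoint")
    for idx in (group_a, group_b):
        for i in idx:
            if not structure.atoms[i].is_heavy:
                raise ValueError(f"selection contains hydrogen atom index {i}; contacts are heavy-atom only")
    ii, _, _ = pairs_within(
        frame.coordinates[group_a], frame.coordinates[group_b], cfg.cutoff, frame.box, strict=True
    )
    return int(ii.size)


def contact_series(
    traj: Trajectory,
    protein_atoms: Optional[np.ndarray] = None,
    sheet_atoms: Optional[np.ndarray] = None,
    cfg: Optional[ContactConfig] = None,
    per_chain: bool = False,
) -> FrameSeries:
    """Per-frame protein–sheet contact totals, optionally split by chain.

    Chain values sum exactly to the total at every frame (chains partition
    the protein selection).
    """
    cfg = cfg or ContactConfig()
    s = traj.structure
    if protein_atoms is None:
        protein_atoms = s.group_heavy_atoms("protein")
    if sheet_atoms is None:
        sheet_atoms = s.group_heavy_atoms("graphene")
    protein_atoms = np.asarray(protein_atoms, dtype=np.intp)
    sheet_atoms = np.asarray(sheet_atoms, dtype=np.intp)
    chain_of_atom = {i: s.residues[_respos(s, s.atoms[i].residue_index)].chain_id for i in protein_atoms}
    chains = sorted(set(chain_of_atom.values())) if per_chain else []
    total = np.zeros(traj.n_frames)
    per = {c: np.zeros(traj.n_frames) for c in chains}
    for fi, frame in enumerate(traj.frames):
        ii, _, _ = pairs_within(
            frame.coordinates[protein_atoms], frame.coordinates[sheet_atoms], cfg.cutoff, frame.box, strict=True
        )
        total[fi] = ii.size
        if per_chain:
            for i in ii:
                per[chain_of_atom[int(protein_atoms[i])]][fi] += 1
    return FrameSeries(frame_times=traj.times(), total=total, per_chain=per, kind="contacts")


def _respos(structure: Structure, residue_index: int) -> int:
    # residue .index values coincide with list position for all builders here
    r = structure.residues[residue_index] if residue_index < len(structure.residues) else None
    if r is not None and r.index == residue_index:
        return residue_index
    for pos, r in enumerate(structure.residues):
        if r.index == residue_index:
            return pos
    raise KeyError(residue_index)


def contact_probability(
    traj: Trajectory,
    residues: Optional[Sequence[Residue]] = None,
    sheet_atoms: Optional[np.ndarray] = None,
    cfg: Optional[ContactConfig] = None,
    window: Optional[tuple[int, int]] = None,
) -> ResidueSeries:
    """Fraction of window frames in which each residue touches the sheet.

    A residue is 'in contact' in a frame when it has ≥ 1 heavy-atom pair with
    the sheet below the cutoff. Returned as a one-column ResidueSeries
    (kind='probability'); the window defaults to the full trajectory.
    """
    cfg = cfg or ContactConfig()
    s = traj.structure
    if residues is None:
        residues = s.protein_residues()
    if sheet_atoms is None:
        sheet_atoms = s.group_heavy_atoms("graphene")
    sheet_atoms = np.asarray(sheet_atoms, dtype=np.intp)
    if window is None:
        window = (0, traj.n_frames)
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("empty frame window")
    res_atoms = [np.asarray([i for i in r.atom_indices if s.atoms[i].is_heavy], dtype=np.intp) for r in residues]
    all_idx = np.concatenate(res_atoms)
    owner = np.concatenate([np.full(a.size, k, dtype=np.intp) for k, a in enumerate(res_atoms)])
    hits = np.zeros(len(residues))
    for fi in range(w0, w1):
        frame = traj.frames[fi]
        ii, _, _ = pairs_within(
            frame.coordinates[all_idx], frame.coordinates[sheet_atoms], cfg.cutoff, frame.box, strict=True
        )
        touched = np.unique(owner[ii])
        hits[touched] += 1
    prob = hits / (w1 - w0)
    return ResidueSeries(
        residue_indices=np.array([r.index for r in residues]),
        frame_times=np.array([0.0]),
        values=prob[:, None],
        kind="probability",
        residue_labels=[f"{r.chain_id}:{r.name}-{r.index}" for r in residues],
    )


def sasa(
    coordinates: np.ndarray,
    elements: Sequence[str],
    cfg: Optional[ContactConfig] = None,
) -> float:
    """Total Shrake–Rupley solvent-accessible surface area (Å²)."""
    import biotite.structure as struc

    cfg = cfg or ContactConfig()
    coordinates = np.asarray(coordinates, dtype=float)
    n = coordinates.shape[0]
    try:
        radii = np.array([cfg.radii[e] for e in elements], dtype=float)
    except KeyError as exc:
        raise KeyError(f"no van der Waals radius configured for element {exc.args[0]!r}") from None
    arr = struc.AtomArray(n)
    arr.coord = coordinates
    arr.element = np.asarray(elements, dtype="U2")
    per_atom = struc.sasa(
        arr,
        probe_radius=cfg.probe_radius,
        vdw_radii=radii,
        point_number=cfg.n_sphere_points,
    )
    return float(np.nansum(per_atom))


def contact_surface_area(
    frame: Frame,
    structure: Structure,
    protein_atoms: Optional[np.ndarray] = None,
    sheet_atoms: Optional[np.ndarray] = None,
    cfg: Optional[ContactConfig] = None,
) -> float:
    """Buried-SASA contact area: (SASA_A + SASA_B − SASA_AB) / 2, in Å²."""
    cfg = cfg or ContactConfig()
    if protein_atoms is None:
        protein_atoms = structure.group_heavy_atoms("protein")
    if sheet_atoms is None:
        sheet_atoms = structure.group_heavy_atoms("graphene")
    protein_atoms = np.asarray(protein_atoms, dtype=np.intp)
    sheet_atoms = np.asarray(sheet_atoms, dtype=np.intp)
    elem = [a.element for a in structure.atoms]
    ea = [elem[i] for i in protein_atoms]
    eb = [elem[i] for i in sheet_atoms]
    xa = frame.coordinates[protein_atoms]
    xb = frame.coordinates[sheet_atoms]
    sa = sasa(xa, ea, cfg)
    sb = sasa(xb, eb, cfg)
    sab = sasa(np.vstack([xa, xb]), ea + eb, cfg)
    return max(0.0, 0.5 * (sa + sb - sab))
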