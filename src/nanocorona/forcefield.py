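"""Per-residue protein–graphene van der Waals (12-6 Lennard-Jones) energies.

The graphene carbons are uncharged LJ particles, so dispersion is the only
protein–sheet term. Protein heavy atoms carry a compact per-element LJ table
(C/N/O/S/P defaults of CHARMM-like magnitude, fully overridable from a
plain-text parameter file); cross parameters follow Lorentz–Berthelot
(σ arithmetic mean, ε geometric mean) and the interaction is truncated
sharply at the cutoff (default 12 Å). Energies are reported in kcal/mol by
default.

This element-level table is the package's one deliberate simplification of
a full force field: per-residue rankings depend on relative dispersion
strengths, which an element table preserves, but absolute energies are
approximate. Full atom-typing is out of scope.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .graphene import LJParams
from .neighbors import displacement, pairs_within
from .series import ResidueSeries
from .structures import Frame, Residue, Structure, Trajectory

__all__ = [
    "LJTable",
    "EnergyConfig",
    "pair_energy",
    "lorentz_berthelot",
    "residue_graphene_energy",
    "energy_series",
    "adsorption_energy_drop",
    "KJ_PER_KCAL",
]

KJ_PER_KCAL = 4.184


@dataclass
class LJTable:
    """Element → LJParams mapping (σ Å, ε kJ/mol), Lorentz–Berthelot combining."""

    params: dict[str, LJParams] = field(default_factory=dict)
    combining_rule: str = "lorentz-berthelot"

    def __getitem__(self, element: str) -> LJParams:
        try:
            return self.params[element.capitalize()]
        except KeyError:
            raise KeyError(
                f"no Lennard-Jones parameters for element {element!r}; "
                "add an entry to the parameter table"
            ) from None

    @classmethod
    def default(cls) -> "LJTable":
        """Load the packaged element table (data/lj_params.txt)."""
        with resources.files("nanocorona.data").joinpath("lj_params.txt").open() as fh:
            return cls.from_text(fh.read())

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "LJTable":
        return cls.from_text(Path(path).read_text())

    @classmethod
    def from_text(cls, text: str) -> "LJTable":
        """Parse ``element sigma_nm epsilon_kJmol`` lines (# comments)."""
        params: dict[str, LJParams] = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"LJ parameter file line {lineno}: expected 'element sigma_nm epsilon_kJmol'")
            elem, sigma_nm, eps = parts
            params[elem.capitalize()] = LJParams(sigma=float(sigma_nm) * 10.0, epsilon=float(eps))
        return cls(params)


@dataclass
class EnergyConfig:
    """vdW cutoff (Å) and reporting unit."""

    cutoff: float = 12.0
    unit: str = "kcal/mol"  # or "kJ/mol"
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.unit not in {"kcal/mol", "kJ/mol"}:
            raise ValueError(f"unknown energy unit {self.unit!r}")

    def from_kj(self, value):
        return value / KJ_PER_KCAL if self.unit == "kcal/mol" else value


def lorentz_berthelot(p_i: LJParams, p_j: LJParams) -> LJParams:
    return LJParams(sigma=0.5 * (p_i.sigma + p_j.sigma), epsilon=np.sqrt(p_i.epsilon * p_j.epsilon))


def pair_energy(r: float, p_i: LJParams, p_j: LJParams) -> float:
    """12-6 LJ energy V(r) = 4ε[(σ/r)^12 − (σ/r)^6] in kJ/mol, σ/ε combined
    by Lorentz–Berthelot. No cutoff is applied here."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    c = lorentz_berthelot(p_i, p_j)
    x = (c.sigma / r) ** 6
    return float(4.0 * c.epsilon * (x * x - x))


def _lj_sum(d: np.ndarray, sigma: np.ndarray, epsilon: np.ndarray) -> float:
    x = (sigma / d) ** 6
    return float(np.sum(4.0 * epsilon * (x * x - x)))


def _residue_atoms(structure: Structure, residue: Residue, include_h: bool) -> np.ndarray:
    idx = residue.atom_indices
    if include_h:
        return np.asarray(idx, dtype=np.intp)
    return np.asarray([i for i in idx if structure.atoms[i].is_heavy], dtype=np.intp)


def _cross_params(structure: Structure, atom_idx: np.ndarray, table: LJTable, sheet_lj: LJParams):
    sig = np.empty(atom_idx.size)
    eps = np.empty(atom_idx.size)
    for k, i in enumerate(atom_idx):
        c = lorentz_berthelot(table[structure.atoms[i].element], sheet_lj)
        sig[k] = c.sigma
        eps[k] = c.epsilon
    return sig, eps


def residue_graphene_energy(
    frame: Frame,
    structure: Structure,
    residue: Residue,
    sheet_atoms: np.ndarray,
    cfg: EnergyConfig,
    table: LJTable,
    sheet_lj: Optional[LJParams] = None,
) -> float:
    """Total vdW energy between one residue and the sheet atoms, truncated at
    the cutoff, minimum-image when the frame carries a box."""
    sheet_atoms = np.asarray(sheet_atoms, dtype=np.intp)
    if sheet_atoms.size == 0:
        raise ValueError("sheet atom selection is empty")
    if sheet_lj is None:
        from .graphene import GRAPHENE_LJ

        sheet_lj = GRAPHENE_LJ
    res_idx = _residue_atoms(structure, residue, cfg.include_hydrogens)
    if res_idx.size == 0:
        return 0.0
    sig, eps = _cross_params(structure, res_idx, table, sheet_lj)
    xa = frame.coordinates[res_idx]
    xb = frame.coordinates[sheet_atoms]
    ii, _, d = pairs_within(xa, xb, cfg.cutoff, frame.box, strict=False)
    if ii.size == 0:
        return 0.0
    e_kj = _lj_sum(d, sig[ii], eps[ii])
    return float(cfg.from_kj(e_kj))


def energy_series(
    traj: Trajectory,
    residues: Optional[Sequence[Residue]] = None,
    sheet_atoms: Optional[np.ndarray] = None,
    cfg: Optional[EnergyConfig] = None,
    table: Optional[LJTable] = None,
    sheet_lj: Optional[LJParams] = None,
) -> ResidueSeries:
    """Per-residue, per-frame vdW energy with the graphene sheet."""
    cfg = cfg or EnergyConfig()
    table = table or LJTable.default()
    structure = traj.structure
    if residues is None:
        residues = structure.protein_residues()
    if sheet_atoms is None:
        sheet_atoms = structure.group_heavy_atoms("graphene")
    sheet_atoms = np.asarray(sheet_atoms, dtype=np.intp)
    if len(residues) == 0 or sheet_atoms.size == 0:
        raise ValueError("empty residue or sheet selection")
    if sheet_lj is None:
        from .graphene import GRAPHENE_LJ

        sheet_lj = GRAPHENE_LJ

    res_atom_idx = [_residue_atoms(structure, r, cfg.include_hydrogens) for r in residues]
    all_idx = np.concatenate([i for i in res_atom_idx if i.size]) if res_atom_idx else np.empty(0, np.intp)
    owner = np.concatenate(
        [np.full(i.size, k, dtype=np.intp) for k, i in enumerate(res_atom_idx)]
    ) if all_idx.size else np.empty(0, np.intp)
    sig, eps = _cross_params(structure, all_idx, table, sheet_lj)

    values = np.zeros((len(residues), traj.n_frames))
    for fi, frame in enumerate(traj.frames):
        xa = frame.coordinates[all_idx]
        xb = frame.coordinates[sheet_atoms]
        ii, _, d = pairs_within(xa, xb, cfg.cutoff, frame.box, strict=False)
        if ii.size == 0:
            continue
        x = (sig[ii] / d) ** 6
        e = 4.0 * eps[ii] * (x * x - x)
        np.add.at(values[:, fi], owner[ii], e)
    values = cfg.from_kj(values)
    return ResidueSeries(
        residue_indices=np.array([r.index for r in residues]),
        frame_times=traj.times(),
        values=values,
        kind="energy",
        residue_labels=[f"{r.chain_id}:{r.name}-{r.index}" for r in residues],
    )


def adsorption_energy_drop(
    replica_rows: Sequence[np.ndarray],
    baseline: tuple[int, int],
    plateau: tuple[int, int],
) -> tuple[np.ndarray, float, float]:
    """Energy drop (baseline-window mean − plateau-window mean) per replica,
    plus the cross-replica mean and sample standard deviation.

    A positive drop means the energy decreased (became more favourable)
    between the two windows.
    """
    b0, b1 = baseline
    p0, p1 = plateau
    if b1 <= b0 or p1 <= p0:
        raise ValueError("windows must contain at least one frame")
    if max(b0, p0) < min(b1, p1):
        raise ValueError("baseline and plateau windows must not overlap")
    drops = np.array([float(np.mean(row[b0:b1]) - np.mean(row[p0:p1])) for row in replica_rows])
    mean = float(drops.mean())
    sd = float(drops.std(ddof=1)) if drops.size > 1 else 0.0
    return drops, mean, sd
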