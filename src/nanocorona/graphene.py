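"""Rectangular single-layer graphene sheet generator.

The sheet is a rigid honeycomb lattice with a four-atom rectangular
repeating cell (x-period 3·a, y-period √3·a for bond length a), armchair
edge along x. Carbons carry the uncharged Lennard-Jones parameters used for
graphene in protein-adsorption simulations: σ = 3.4 Å, ε = 0.3598 kJ/mol.
Edge atoms are left unsaturated; the builder emits static geometry only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structures import Atom, Frame, Residue, Structure

__all__ = ["LJParams", "GrapheneSheet", "build_sheet", "sheet_as_structure", "GRAPHENE_LJ", "CC_BOND_LENGTH"]

#: accepted equilibrium graphene C–C bond length (Å)
CC_BOND_LENGTH = 1.42


@dataclass(frozen=True)
class LJParams:
    """12-6 Lennard-Jones parameters: σ in Å, ε in kJ/mol."""

    sigma: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.epsilon <= 0:
            raise ValueError("sigma and epsilon must be positive")


#: graphene carbon: σcc = 0.34 nm, εcc = 0.3598 kJ/mol
GRAPHENE_LJ = LJParams(sigma=3.4, epsilon=0.3598)


@dataclass
class GrapheneSheet:
    """Generated coplanar carbon lattice plus its LJ parameters."""

    carbon_coordinates: np.ndarray  # (n, 3), Å
    bond_length: float
    width: float  # achieved x-extent (one lattice period), Å
    height: float  # achieved y-extent, Å
    lj: LJParams = GRAPHENE_LJ

    @property
    def n_atoms(self) -> int:
        return self.carbon_coordinates.shape[0]


def build_sheet(
    width: float,
    height: float,
    bond_length: float = CC_BOND_LENGTH,
    z: float = 0.0,
    lj: LJParams = GRAPHENE_LJ,
) -> GrapheneSheet:
    """Build a rectangular honeycomb sheet of roughly width × height (Å).

    The achieved extents are the nearest whole number of lattice periods
    (x-period 3·a, y-period √3·a); atom count is 4 per rectangular cell.
    """
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    a = bond_length
    px, py = 3.0 * a, math.sqrt(3.0) * a
    if width < px - 1e-9 or height < py - 1e-9:
        raise ValueError(
            f"requested extent {width:.2f} × {height:.2f} Å is below one unit cell ({px:.2f} × {py:.2f} Å)"
        )
    nx = max(1, int(round(width / px)))
    ny = max(1, int(round(height / py)))
    basis = np.array(
        [
            [0.0, 0.0],
            [a, 0.0],
            [1.5 * a, 0.5 * py],
            [2.5 * a, 0.5 * py],
        ]
    )
    cells = np.array([[i * px, j * py] for i in range(nx) for j in range(ny)])
    xy = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 2)
    coords = np.column_stack([xy, np.full(len(xy), float(z))])
    return GrapheneSheet(
        carbon_coordinates=coords,
        bond_length=a,
        width=nx * px,
        height=ny * py,
        lj=lj,
    )


def sheet_as_structure(sheet: GrapheneSheet, resname: str = "GRA", chain_id: str = "G") -> tuple[Structure, Frame]:
    """Wrap the sheet as a one-residue Structure of carbon atoms."""
    n = sheet.n_atoms
    atoms = [Atom(serial=i + 1, name=f"C{i + 1}", element="C", residue_index=0) for i in range(n)]
    residues = [
        Residue(
            index=0,
            name=resname,
            chain_id=chain_id,
            atom_indices=np.arange(n, dtype=np.intp),
            group_label="graphene",
        )
    ]
    return Structure(atoms, residues), Frame(coordinates=sheet.carbon_coordinates.copy())
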