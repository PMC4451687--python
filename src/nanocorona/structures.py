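"""Atom/residue/chain data model shared by every metric.

A :class:`Structure` is the static topology (atoms grouped into residues,
residues grouped into chains); coordinates live in :class:`Frame` objects so
that one topology can be shared by all frames of a :class:`Trajectory`.
Lengths are ångström throughout, times nanoseconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Frame",
    "Trajectory",
    "infer_element",
    "AMINO_ACIDS",
    "WATER_RESNAMES",
    "BACKBONE_NAMES",
]

#: three-letter codes treated as protein residues (standard 20 + common
#: histidine protonation-state aliases)
AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL HSD HSE HSP HID HIE HIP""".split()
)

#: residue names recognised as water across common force-field dialects
WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT", "TIP3", "TIP", "SPC"})

#: backbone atom names excluded from side-chain selections (plus the
#: terminal oxygens OXT/OT1/OT2 and backbone hydrogens)
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "OT1", "OT2", "H", "HN", "HA", "HA1", "HA2", "H1", "H2", "H3"})

_TWO_LETTER_ELEMENTS = frozenset(
    {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CA", "CU", "NI", "CO", "SE", "SI", "LI", "AL", "CD", "HG"}
)
_ONE_LETTER_ELEMENTS = frozenset("HCNOSPFKIB")


def infer_element(atom_name: str, residue_name: str = "") -> str:
    """Infer the chemical element from a PDB-style atom name.

    Leading digits are stripped; within amino-acid and water residues the
    first alphabetic character decides (so ``CA`` is the α-carbon, not
    calcium); elsewhere a two-letter element match is tried first.
    """
    s = atom_name.strip().lstrip("0123456789")
    if not s:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    s = s.upper()
    resname = residue_name.strip().upper()
    if resname in AMINO_ACIDS or resname in WATER_RESNAMES:
        c = s[0]
        if c in _ONE_LETTER_ELEMENTS:
            return c.capitalize()
        raise ValueError(f"cannot infer element from atom name {atom_name!r} in residue {residue_name!r}")
    if s[:2] in _TWO_LETTER_ELEMENTS:
        return s[:2].capitalize()
    if s[0] in _ONE_LETTER_ELEMENTS:
        return s[0].capitalize()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass(frozen=True)
class Atom:
    """One atom of the topology; coordinates are held per-frame, not here."""

    serial: int
    name: str
    element: str
    residue_index: int

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Residue:
    """A residue: contiguous atom-index range plus identity and role."""

    index: int
    name: str
    chain_id: str
    atom_indices: np.ndarray  # indices into Structure.atoms
    group_label: str  # protein | graphene | water | other

    def sidechain_atom_indices(self, structure: "Structure") -> np.ndarray:
        """Indices of side-chain atoms (empty for non-protein groups and
        for glycine, whose side chain is a single hydrogen)."""
        if self.group_label != "protein":
            return np.empty(0, dtype=np.intp)
        keep = [
            i
            for i in self.atom_indices
            if structure.atoms[i].name.strip().upper() not in BACKBONE_NAMES
        ]
        return np.asarray(keep, dtype=np.intp)


@dataclass
class Structure:
    """Ordered atoms partitioned into ordered residues grouped by chain."""

    atoms: list[Atom]
    residues: list[Residue]

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials are not unique within the structure")
        covered = np.concatenate([r.atom_indices for r in self.residues]) if self.residues else np.empty(0, dtype=np.intp)
        if sorted(covered.tolist()) != list(range(len(self.atoms))):
            raise ValueError("residue atom-index ranges do not partition the atom list")
        for r in self.residues:
            for i in r.atom_indices:
                if self.atoms[i].residue_index != r.index:
                    raise ValueError(f"atom {i} disagrees with residue {r.index} about membership")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    # ---- selections -----------------------------------------------------
    def heavy_atom_indices(self, residue_filter=None) -> np.ndarray:
        out = []
        for r in self.residues:
            if residue_filter is not None and not residue_filter(r):
                continue
            out.extend(i for i in r.atom_indices if self.atoms[i].is_heavy)
        return np.asarray(out, dtype=np.intp)

    def group_heavy_atoms(self, group_label: str) -> np.ndarray:
        return self.heavy_atom_indices(lambda r: r.group_label == group_label)

    def chain_heavy_atoms(self, chain_id: str, group_label: str = "protein") -> np.ndarray:
        return self.heavy_atom_indices(
            lambda r: r.group_label == group_label and r.chain_id == chain_id
        )

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.group_label == "protein"]

    def water_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.group_label == "water"]

    def residue_by_index(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"no residue with index {index}")

    def merged_with(self, other: "Structure") -> "Structure":
        """Concatenate two topologies (used to combine protein + sheet)."""
        offset_atoms = len(self.atoms)
        offset_res = max((r.index for r in self.residues), default=-1) + 1
        atoms = list(self.atoms)
        residues = [
            Residue(r.index, r.name, r.chain_id, np.asarray(r.atom_indices), r.group_label)
            for r in self.residues
        ]
        for r in other.residues:
            new_idx = r.index + offset_res
            new_atom_indices = np.asarray(r.atom_indices) + offset_atoms
            for i in r.atom_indices:
                a = other.atoms[i]
                atoms.append(Atom(a.serial + offset_atoms, a.name, a.element, new_idx))
            residues.append(Residue(new_idx, r.name, r.chain_id, new_atom_indices, r.group_label))
        # renumber serials to stay unique
        atoms = [Atom(i + 1, a.name, a.element, a.residue_index) for i, a in enumerate(atoms)]
        return Structure(atoms, residues)


def classify_group(residue_name: str, graphene_resnames: Iterable[str] = ("GRA",)) -> str:
    name = residue_name.strip().upper()
    if name in AMINO_ACIDS:
        return "protein"
    if name in WATER_RESNAMES:
        return "water"
    if name in {g.upper() for g in graphene_resnames}:
        return "graphene"
    return "other"


@dataclass
class Frame:
    """One coordinate set (Å) with an optional orthorhombic box (Å)."""

    coordinates: np.ndarray
    box: Optional[np.ndarray] = None
    time: Optional[float] = None  # ns

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n_atoms, 3) array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise ValueError("box must hold three orthorhombic edge lengths")
            if not np.all(self.box > 0):
                raise ValueError("box lengths must be strictly positive")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """Ordered frames sharing one Structure."""

    structure: Structure
    frames: list[Frame]

    def __post_init__(self) -> None:
        n = self.structure.n_atoms
        for k, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {k}: coordinate count {f.n_atoms} does not match structure atom count {n}"
                )
        times = [f.time for f in self.frames if f.time is not None]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def times(self) -> np.ndarray:
        return np.array(
            [f.time if f.time is not None else float(k) for k, f in enumerate(self.frames)]
        )


def build_structure(
    names: Sequence[str],
    resnames: Sequence[str],
    resids: Sequence[int],
    chain_ids: Sequence[str],
    elements: Optional[Sequence[Optional[str]]] = None,
    graphene_resnames: Iterable[str] = ("GRA",),
) -> Structure:
    """Assemble a Structure from parallel per-atom arrays.

    Consecutive atoms sharing (resid, resname, chain) form a residue; this is
    the convention of every reader and of the synthetic generator.
    """
    n = len(names)
    if not (len(resnames) == len(resids) == len(chain_ids) == n):
        raise ValueError("per-atom arrays must have equal length")
    if n == 0:
        raise ValueError("empty input: structure has zero atoms")
    atoms: list[Atom] = []
    residues: list[Residue] = []
    current_key = None
    current_atoms: list[int] = []

    def flush() -> None:
        if current_key is None:
            return
        resname, chain = current_key[1], current_key[2]
        residues.append(
            Residue(
                index=len(residues),
                name=resname,
                chain_id=chain,
                atom_indices=np.asarray(current_atoms, dtype=np.intp),
                group_label=classify_group(resname, graphene_resnames),
            )
        )

    for i in range(n):
        key = (int(resids[i]), str(resnames[i]).strip(), str(chain_ids[i]).strip())
        if key != current_key:
            flush()
            current_key = key
            current_atoms = []
        elem = None
        if elements is not None:
            e = elements[i]
            elem = str(e).strip().capitalize() if e is not None and str(e).strip() else None
        if not elem:
            elem = infer_element(names[i], resnames[i])
        atoms.append(Atom(serial=i + 1, name=str(names[i]).strip(), element=elem, residue_index=len(residues)))
        current_atoms.append(i)
    flush()
    return Structure(atoms, residues)
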