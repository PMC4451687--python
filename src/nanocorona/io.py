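"""Structure and trajectory I/O.

PDB (single- and multi-model) and XYZ are read and written through
MDAnalysis and normalised into the package's own :class:`Structure` /
:class:`Trajectory` model; any trajectory format MDAnalysis understands can
be ingested the same way. Tables go out as TSV.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .series import FrameSeries, ResidueSeries
from .structures import Frame, Structure, Trajectory, build_structure

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_table",
]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed as the named format."""


def _load_universe(path: Union[str, Path], fmt: Optional[str] = None):
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(str(path), format=fmt)
    except FileNotFoundError:
        raise
    except Exception as exc:  # MDAnalysis raises assorted types on bad input
        raise ParseError(f"parse error in {path}: {exc}") from exc


def _box_from_dimensions(dims) -> Optional[np.ndarray]:
    if dims is None:
        return None
    dims = np.asarray(dims, dtype=float)
    if dims.size < 3 or not np.all(dims[:3] > 0):
        return None
    # only orthorhombic boxes are meaningful downstream
    if dims.size >= 6 and not np.allclose(dims[3:6], 90.0, atol=1e-3):
        return None
    return dims[:3].copy()


def read_structure(
    path: Union[str, Path],
    format: str = "pdb",
    graphene_resnames: Iterable[str] = ("GRA",),
) -> tuple[Structure, Frame]:
    """Read a structure file; returns the topology plus its first frame.

    Elements are taken from the file when present, otherwise inferred from
    atom names (hydrogens are retained but flagged non-heavy).
    """
    if format.lower() not in {"pdb", "xyz"}:
        raise ValueError(f"unsupported structure format: {format!r}")
    u = _load_universe(path, fmt=format.upper())
    if u.atoms.n_atoms == 0:
        raise ParseError(f"empty input: {path} contains zero atoms")
    structure = _structure_from_universe(u, graphene_resnames)
    frame = Frame(
        coordinates=u.atoms.positions.astype(float),
        box=_box_from_dimensions(u.dimensions),
    )
    return structure, frame


def _structure_from_universe(u, graphene_resnames: Iterable[str]) -> Structure:
    atoms = u.atoms
    names = [str(n) for n in atoms.names]
    try:
        resnames = [str(r) for r in atoms.resnames]
    except AttributeError:
        resnames = ["UNK"] * len(names)
    try:
        resids = [int(r) for r in atoms.resids]
    except AttributeError:
        resids = [1] * len(names)
    chain_ids = None
    for attr in ("chainIDs", "segids"):
        try:
            chain_ids = [str(c).strip() or "A" for c in getattr(atoms, attr)]
            break
        except AttributeError:
            continue
    if chain_ids is None:
        chain_ids = ["A"] * len(names)
    elements = None
    try:
        elements = [str(e) for e in atoms.elements]
    except AttributeError:
        pass
    return build_structure(names, resnames, resids, chain_ids, elements, graphene_resnames)


def read_trajectory(
    path: Union[str, Path],
    structure: Optional[Structure] = None,
    format: Optional[str] = None,
    graphene_resnames: Iterable[str] = ("GRA",),
    stride: int = 1,
) -> Trajectory:
    """Read a multi-frame coordinate file into a Trajectory.

    When ``structure`` is given, every frame's atom count is checked against
    it; otherwise the topology is taken from the file itself. Frames without
    a box get ``box=None`` and minimum-image logic is disabled downstream.
    """
    if format is None:
        format = Path(path).suffix.lstrip(".").lower() or "pdb"
    u = _load_universe(path, fmt=format.upper())
    if structure is None:
        structure = _structure_from_universe(u, graphene_resnames)
    frames: list[Frame] = []
    for k, ts in enumerate(u.trajectory):
        if k % stride:
            continue
        if ts.positions.shape[0] != structure.n_atoms:
            raise ValueError(
                f"frame {k}: atom count {ts.positions.shape[0]} does not match "
                f"structure atom count {structure.n_atoms}"
            )
        frames.append(
            Frame(
                coordinates=ts.positions.astype(float),
                box=_box_from_dimensions(ts.dimensions),
            )
        )
    if not frames:
        raise ParseError(f"{path} contains no frames")
    return Trajectory(structure, frames)


def _universe_from(structure: Structure, frame: Frame):
    import MDAnalysis as mda

    n = structure.n_atoms
    resindex = np.array([a.residue_index for a in structure.atoms])
    # residue indices must be 0..n_res-1 in order for Universe.empty
    order = {r.index: i for i, r in enumerate(structure.residues)}
    resindex = np.array([order[i] for i in resindex])
    segidx = np.zeros(len(structure.residues), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n,
            n_residues=len(structure.residues),
            atom_resindex=resindex,
            n_segments=1,
            residue_segindex=segidx,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in structure.atoms])
        u.add_TopologyAttr("elements", [a.element for a in structure.atoms])
        u.add_TopologyAttr("resnames", [r.name for r in structure.residues])
        u.add_TopologyAttr("resids", [(i % 9999) + 1 for i in range(len(structure.residues))])
        u.add_TopologyAttr("chainIDs", [structure.residues[i].chain_id[:1] or "A" for i in resindex])
        u.atoms.positions = frame.coordinates.astype(np.float32)
        if frame.box is not None:
            u.dimensions = np.array([*frame.box, 90.0, 90.0, 90.0], dtype=np.float32)
    return u


def write_structure(structure: Structure, frame: Frame, path: Union[str, Path]) -> None:
    """Write a single-model PDB (or XYZ, by extension)."""
    import MDAnalysis as mda

    u = _universe_from(structure, frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=structure.n_atoms) as w:
            w.write(u.atoms)


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write a multi-model PDB or a multi-frame XYZ, chosen by extension."""
    import MDAnalysis as mda

    u = _universe_from(traj.structure, traj.frames[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.structure.n_atoms, multiframe=True) as w:
            for f in traj.frames:
                u.atoms.positions = f.coordinates.astype(np.float32)
                if f.box is not None:
                    u.dimensions = np.array([*f.box, 90.0, 90.0, 90.0], dtype=np.float32)
                w.write(u.atoms)


def write_table(
    series: Union[ResidueSeries, FrameSeries, pd.DataFrame],
    path: Union[str, Path],
    long_form: bool = True,
) -> None:
    """Write a series as TSV with a header row, 6 significant digits.

    ResidueSeries goes out in long form (one row per residue-frame pair) by
    default, FrameSeries as one row per frame.
    """
    if isinstance(series, ResidueSeries):
        if series.values.size == 0:
            raise ValueError("empty series")
        df = series.to_long_frame() if long_form else _wide(series)
    elif isinstance(series, FrameSeries):
        if series.total.size == 0:
            raise ValueError("empty series")
        df = series.to_frame()
    elif isinstance(series, pd.DataFrame):
        if series.empty:
            raise ValueError("empty series")
        df = series
    else:
        raise TypeError(f"cannot serialise {type(series).__name__}")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _wide(series: ResidueSeries) -> pd.DataFrame:
    labels = series.residue_labels or [str(i) for i in series.residue_indices]
    data = {"time_ns": series.frame_times}
    for ri, lab in enumerate(labels):
        data[lab] = series.values[ri]
    return pd.DataFrame(data)
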