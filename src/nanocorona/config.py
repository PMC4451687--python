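"""Run-configuration parsing and validation for the analysis pipeline.

The configuration is a YAML mapping with one section per stage. Every key
is optional — defaults encode the standard analysis parameters (6.0 Å
contact cutoff, 5 Å solvation shell, 12 Å vdW cutoff, −10 kcal/mol energy
rule in 2 of 3 replicas, 0.6 probability rule) — but unknown keys are
rejected, each violation named with its key path.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .contacts import ContactConfig
from .forcefield import EnergyConfig, LJTable
from .keyres import TaggingConfig
from .solvation import FSSConfig

__all__ = ["RunConfig", "ConfigError", "validate", "load_config"]


class ConfigError(ValueError):
    """A configuration invariant violation, named with its key path."""


@dataclass
class AnalysisOptions:
    equilibration_frames: int = 0
    stride: int = 1
    per_chain: bool = True
    surface_area: bool = False  # SASA-based contact area is costly; opt-in
    report_mode: str = "union"
    native_cutoff: float = 6.0
    min_separation: int = 3
    superpose_per_chain: bool = True
    solvation: str = "auto"  # auto | on | off


@dataclass
class RunConfig:
    structure_path: Path
    trajectory_paths: list[Path]
    reference_path: Optional[Path]
    output_dir: Path
    graphene_resnames: list[str]
    contacts: ContactConfig
    energy: EnergyConfig
    fss: FSSConfig
    tagging: TaggingConfig
    analysis: AnalysisOptions
    lj_params_path: Optional[Path] = None
    log_level: str = "INFO"

    def lj_table(self) -> LJTable:
        if self.lj_params_path is not None:
            return LJTable.from_file(self.lj_params_path)
        return LJTable.default()


_SCHEMA: dict[str, set[str]] = {
    "": {"inputs", "selections", "contacts", "energy", "native_contacts", "fss", "tagging", "analysis", "output"},
    "inputs": {"structure", "trajectories", "reference"},
    "selections": {"graphene_resnames"},
    "contacts": {"cutoff", "probe_radius", "n_sphere_points"},
    "energy": {"cutoff", "unit", "include_hydrogens", "lj_params"},
    "native_contacts": {"cutoff", "min_separation"},
    "fss": {"shell_radius", "water_site", "inclusive_boundary"},
    "tagging": {
        "energy_threshold",
        "min_replicas",
        "total_replicas",
        "probability_threshold",
        "window",
        "histidine_basic",
    },
    "analysis": {
        "equilibration_frames",
        "stride",
        "per_chain",
        "surface_area",
        "report_mode",
        "superpose_per_chain",
        "solvation",
    },
    "output": {"directory", "log_level"},
}


def _check_keys(section: str, mapping: dict) -> None:
    allowed = _SCHEMA[section]
    for k in mapping:
        if k not in allowed:
            path = f"{section}.{k}" if section else str(k)
            raise ConfigError(f"unknown configuration key {path!r}")


def _section(raw: dict, name: str) -> dict:
    v = raw.get(name, {}) or {}
    if not isinstance(v, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    _check_keys(name, v)
    return v


def validate(raw: Union[dict, str, Path], base_dir: Optional[Path] = None) -> RunConfig:
    """Validate a config mapping (or YAML file path) into a RunConfig."""
    if isinstance(raw, (str, Path)):
        return load_config(raw)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys("", raw)
    base = base_dir or Path(".")

    inputs = _section(raw, "inputs")
    structure = inputs.get("structure")
    if structure is None:
        raise ConfigError("inputs.structure is required")
    structure = (base / structure).resolve() if not Path(structure).is_absolute() else Path(structure)
    if not structure.exists():
        raise ConfigError(f"inputs.structure: file not found: {structure}")
    traj_raw = inputs.get("trajectories", [])
    if isinstance(traj_raw, (str, Path)):
        traj_raw = [traj_raw]
    if not traj_raw:
        raise ConfigError("inputs.trajectories must list at least one trajectory")
    trajectories = []
    for t in traj_raw:
        p = (base / t).resolve() if not Path(t).is_absolute() else Path(t)
        if not p.exists():
            raise ConfigError(f"inputs.trajectories: file not found: {p}")
        trajectories.append(p)
    reference = inputs.get("reference")
    if reference is not None:
        reference = (base / reference).resolve() if not Path(reference).is_absolute() else Path(reference)
        if not reference.exists():
            raise ConfigError(f"inputs.reference: file not found: {reference}")

    selections = _section(raw, "selections")
    graphene_resnames = [str(s) for s in selections.get("graphene_resnames", ["GRA"])]

    c = _section(raw, "contacts")
    try:
        contacts = ContactConfig(
            cutoff=float(c.get("cutoff", 6.0)),
            probe_radius=float(c.get("probe_radius", 1.4)),
            n_sphere_points=int(c.get("n_sphere_points", 960)),
        )
    except ValueError as exc:
        raise ConfigError(f"contacts: {exc}") from None

    e = _section(raw, "energy")
    try:
        energy = EnergyConfig(
            cutoff=float(e.get("cutoff", 12.0)),
            unit=str(e.get("unit", "kcal/mol")),
            include_hydrogens=bool(e.get("include_hydrogens", False)),
        )
    except ValueError as exc:
        raise ConfigError(f"energy: {exc}") from None
    lj_params = e.get("lj_params")
    if lj_params is not None:
        lj_params = (base / lj_params).resolve() if not Path(lj_params).is_absolute() else Path(lj_params)
        if not lj_params.exists():
            raise ConfigError(f"energy.lj_params: file not found: {lj_params}")

    f = _section(raw, "fss")
    try:
        fss = FSSConfig(
            shell_radius=float(f.get("shell_radius", 5.0)),
            water_site=str(f.get("water_site", "oxygen")),
            inclusive_boundary=bool(f.get("inclusive_boundary", True)),
        )
    except ValueError as exc:
        raise ConfigError(f"fss: {exc}") from None

    t = _section(raw, "tagging")
    window = t.get("window")
    if window is not None:
        window = (int(window[0]), int(window[1]))
    try:
        tagging = TaggingConfig(
            energy_threshold=float(t.get("energy_threshold", -10.0)),
            min_replicas=int(t.get("min_replicas", 2)),
            total_replicas=int(t.get("total_replicas", 3)),
            probability_threshold=float(t.get("probability_threshold", 0.6)),
            window=window,
            histidine_basic=bool(t.get("histidine_basic", True)),
        )
    except ValueError as exc:
        raise ConfigError(f"tagging: {exc}") from None

    nc = _section(raw, "native_contacts")
    a = _section(raw, "analysis")
    try:
        analysis = AnalysisOptions(
            equilibration_frames=int(a.get("equilibration_frames", 0)),
            stride=int(a.get("stride", 1)),
            per_chain=bool(a.get("per_chain", True)),
            surface_area=bool(a.get("surface_area", False)),
            report_mode=str(a.get("report_mode", "union")),
            native_cutoff=float(nc.get("cutoff", 6.0)),
            min_separation=int(nc.get("min_separation", 3)),
            superpose_per_chain=bool(a.get("superpose_per_chain", True)),
            solvation=str(a.get("solvation", "auto")),
        )
    except ValueError as exc:
        raise ConfigError(f"analysis: {exc}") from None
    if analysis.stride < 1:
        raise ConfigError("analysis.stride must be ≥ 1")
    if analysis.equilibration_frames < 0:
        raise ConfigError("analysis.equilibration_frames must be ≥ 0")
    if analysis.report_mode not in {"union", "intersection", "energy-only", "probability-only"}:
        raise ConfigError(f"analysis.report_mode: unknown mode {analysis.report_mode!r}")
    if analysis.solvation not in {"auto", "on", "off"}:
        raise ConfigError(f"analysis.solvation: unknown mode {analysis.solvation!r}")
    if analysis.native_cutoff <= 0:
        raise ConfigError("native_contacts.cutoff must be positive")

    o = _section(raw, "output")
    output_dir = Path(o.get("directory", "nanocorona_out"))
    if not output_dir.is_absolute():
        output_dir = base / output_dir
    log_level = str(o.get("log_level", "INFO")).upper()
    if log_level not in {"DEBUG", "INFO", "WARNING", "ERROR"}:
        raise ConfigError(f"output.log_level: unknown level {log_level!r}")

    return RunConfig(
        structure_path=structure,
        trajectory_paths=trajectories,
        reference_path=reference,
        output_dir=output_dir,
        graphene_resnames=graphene_resnames,
        contacts=contacts,
        energy=energy,
        fss=fss,
        tagging=tagging,
        analysis=analysis,
        lj_params_path=lj_params,
        log_level=log_level,
    )


def load_config(path: Union[str, Path]) -> RunConfig:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return validate(raw, base_dir=path.parent)
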