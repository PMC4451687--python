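"""Key-residue identification across replica simulations.

Two corroborating selection rules tag residues that drive adsorption:

* energy rule — window-averaged vdW energy with the sheet ≤ −10 kcal/mol in
  at least 2 of the 3 replicas;
* probability rule — contact probability with the sheet strictly > 0.6.

Tagged residues are summarised by chemical class; in blood-protein corona
studies the striking observation is how many of them are basic
(arginine/lysine) rather than aromatic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .series import ResidueSeries

__all__ = [
    "TaggingConfig",
    "KeyResidueReport",
    "classify_residue",
    "tag_by_energy",
    "tag_by_probability",
    "compose_report",
]

_BASIC = {"ARG", "LYS"}
_HIS = {"HIS", "HSD", "HSE", "HSP", "HID", "HIE", "HIP"}
_ACIDIC = {"ASP", "GLU"}
_AROMATIC = {"PHE", "TYR", "TRP"}
_HYDROPHOBIC = {"LEU", "ILE", "VAL", "ALA", "MET", "PRO"}
_POLAR = {"SER", "THR", "ASN", "GLN", "CYS", "GLY"}


def classify_residue(name: str, histidine_basic: bool = True) -> str:
    """Chemical class of a standard residue: basic | acidic | aromatic |
    hydrophobic | polar. Histidine counts as basic by default."""
    code = name.strip().upper()
    if code in _BASIC:
        return "basic"
    if code in _HIS:
        return "basic" if histidine_basic else "polar"
    if code in _ACIDIC:
        return "acidic"
    if code in _AROMATIC:
        return "aromatic"
    if code in _HYDROPHOBIC:
        return "hydrophobic"
    if code in _POLAR:
        return "polar"
    raise ValueError(f"unknown residue code {name!r}")


@dataclass
class TaggingConfig:
    energy_threshold: float = -10.0  # kcal/mol, rule is '≤'
    min_replicas: int = 2
    total_replicas: int = 3
    probability_threshold: float = 0.6  # rule is strict '>'
    window: Optional[tuple[int, int]] = None  # defaults to final 25% of frames
    histidine_basic: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_replicas <= self.total_replicas):
            raise ValueError("need 0 < min_replicas <= total_replicas")
        if not (0.0 <= self.probability_threshold <= 1.0):
            raise ValueError("probability threshold must lie in [0, 1]")

    def resolve_window(self, n_frames: int) -> tuple[int, int]:
        if self.window is not None:
            w0, w1 = self.window
            if not (0 <= w0 < w1 <= n_frames):
                raise ValueError(f"window {self.window} invalid for {n_frames} frames")
            return w0, w1
        return (3 * n_frames) // 4, n_frames


def tag_by_energy(
    replica_series: Sequence[ResidueSeries],
    cfg: Optional[TaggingConfig] = None,
) -> set[int]:
    """Residues whose window-averaged energy is ≤ threshold in at least
    ``min_replicas`` replicas."""
    cfg = cfg or TaggingConfig()
    if len(replica_series) < cfg.min_replicas:
        raise ValueError(
            f"{len(replica_series)} replica(s) given but the rule needs at least {cfg.min_replicas}"
        )
    ref = replica_series[0].residue_indices
    for s in replica_series[1:]:
        if not np.array_equal(s.residue_indices, ref):
            raise ValueError("replicas must share a common residue indexing")
    votes = np.zeros(ref.size, dtype=int)
    for s in replica_series:
        w0, w1 = cfg.resolve_window(s.n_frames)
        mean = s.window_mean(w0, w1)
        votes += (mean <= cfg.energy_threshold).astype(int)
    return {int(r) for r in ref[votes >= cfg.min_replicas]}


def tag_by_probability(
    probabilities: Mapping[int, float] | ResidueSeries,
    cfg: Optional[TaggingConfig] = None,
) -> set[int]:
    """Residues with contact probability strictly above the threshold."""
    cfg = cfg or TaggingConfig()
    if isinstance(probabilities, ResidueSeries):
        probabilities = {
            int(i): float(v)
            for i, v in zip(probabilities.residue_indices, probabilities.values[:, -1])
        }
    for r, p in probabilities.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"residue {r}: probability {p} outside [0, 1]")
    return {int(r) for r, p in probabilities.items() if p > cfg.probability_threshold}


@dataclass
class KeyResidueReport:
    """Tagged residues with their cross-replica evidence and class counts."""

    table: pd.DataFrame
    class_counts: dict[str, int]
    mode: str

    @property
    def residue_indices(self) -> set[int]:
        return set(int(i) for i in self.table["residue_index"])

    def summary(self) -> str:
        lines = [f"key residues ({self.mode} rule): {len(self.table)}"]
        for cls in ("basic", "acidic", "aromatic", "hydrophobic", "polar"):
            n = self.class_counts.get(cls, 0)
            if n:
                lines.append(f"  {cls:12s} {n}")
        for _, row in self.table.iterrows():
            lines.append(
                f"  {row['chain']}:{row['name']}-{row['residue_index']} [{row['class']}]"
                f"  rules={row['rules']}"
            )
        return "\n".join(lines)


def compose_report(
    energy_set: set[int],
    probability_set: set[int],
    residue_info: Mapping[int, tuple[str, str]],
    mode: str = "union",
    cfg: Optional[TaggingConfig] = None,
    replica_energy_means: Optional[Mapping[int, Sequence[float]]] = None,
    probabilities: Optional[Mapping[int, float]] = None,
) -> KeyResidueReport:
    """Assemble the report. ``residue_info`` maps residue index → (name,
    chain); mode is union | intersection | energy-only | probability-only."""
    cfg = cfg or TaggingConfig()
    if mode == "union":
        chosen = energy_set | probability_set
    elif mode == "intersection":
        chosen = energy_set & probability_set
    elif mode == "energy-only":
        chosen = set(energy_set)
    elif mode == "probability-only":
        chosen = set(probability_set)
    else:
        raise ValueError(f"unknown report mode {mode!r}")
    rows = []
    counts: dict[str, int] = {}
    for r in sorted(chosen):
        name, chain = residue_info[r]
        cls = classify_residue(name, cfg.histidine_basic)
        counts[cls] = counts.get(cls, 0) + 1
        rules = "+".join(
            tag for tag, hit in (("energy", r in energy_set), ("probability", r in probability_set)) if hit
        )
        row = {
            "residue_index": r,
            "name": name,
            "chain": chain,
            "class": cls,
            "rules": rules,
        }
        if replica_energy_means is not None and r in replica_energy_means:
            for k, e in enumerate(replica_energy_means[r], 1):
                row[f"energy_rep{k}_kcal"] = float(e)
        if probabilities is not None and r in probabilities:
            row["contact_probability"] = float(probabilities[r])
        rows.append(row)
    table = pd.DataFrame(rows)
    return KeyResidueReport(table=table, class_counts=counts, mode=mode)
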