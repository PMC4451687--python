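"""Per-residue, per-frame scalar series — the common output shape.

Contact counts, vdW energies and first-solvation-shell water counts all come
out of the pipeline as a residue × frame matrix tagged with what the values
mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ResidueSeries", "FrameSeries"]


@dataclass
class ResidueSeries:
    """A (residue × frame) value matrix with residue/frame labels.

    ``kind`` tags the value semantics: ``contact`` | ``energy`` | ``fss``.
    """

    residue_indices: np.ndarray
    frame_times: np.ndarray
    values: np.ndarray
    kind: str
    residue_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residue_indices = np.asarray(self.residue_indices, dtype=np.intp)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.values = np.asarray(self.values)
        if self.values.shape != (self.residue_indices.size, self.frame_times.size):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{self.residue_indices.size} residues × {self.frame_times.size} frames"
            )
        if self.residue_labels and len(self.residue_labels) != self.residue_indices.size:
            raise ValueError("residue_labels length mismatch")

    @property
    def n_residues(self) -> int:
        return self.residue_indices.size

    @property
    def n_frames(self) -> int:
        return self.frame_times.size

    def row(self, residue_index: int) -> np.ndarray:
        pos = np.nonzero(self.residue_indices == residue_index)[0]
        if pos.size == 0:
            raise KeyError(f"residue {residue_index} not in series")
        return self.values[pos[0]]

    def window_mean(self, start: int, stop: int) -> np.ndarray:
        """Per-residue mean over frames [start, stop)."""
        if stop <= start:
            raise ValueError("empty window")
        return self.values[:, start:stop].mean(axis=1)

    def to_long_frame(self) -> pd.DataFrame:
        labels = self.residue_labels or [str(i) for i in self.residue_indices]
        rows = []
        for ri, (idx, lab) in enumerate(zip(self.residue_indices, labels)):
            for fi, t in enumerate(self.frame_times):
                rows.append((int(idx), lab, float(t), self.values[ri, fi]))
        return pd.DataFrame(rows, columns=["residue_index", "residue", "time_ns", self.kind])


@dataclass
class FrameSeries:
    """A per-frame scalar series, optionally decomposed by chain."""

    frame_times: np.ndarray
    total: np.ndarray
    per_chain: dict[str, np.ndarray] = field(default_factory=dict)
    kind: str = "value"

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.total = np.asarray(self.total)
        if self.total.shape != self.frame_times.shape:
            raise ValueError("total length does not match frame count")
        for c, v in self.per_chain.items():
            if np.asarray(v).shape != self.frame_times.shape:
                raise ValueError(f"chain {c!r} series length mismatch")

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ns": self.frame_times, self.kind: self.total}
        for c, v in self.per_chain.items():
            data[f"{self.kind}_{c}"] = v
        return pd.DataFrame(data)
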