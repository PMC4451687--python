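"""Simple summary figures for the per-stage tables.

Layouts mirror the usual presentation of adsorption trajectories: total +
per-chain contact series, per-residue energy traces, RMSD/Q panels, and the
paired side-chain-contact / solvation-shell panel for a single residue.
"""
from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .series import FrameSeries, ResidueSeries

__all__ = ["plot_contact_series", "plot_residue_series", "plot_fss_vs_contacts"]


def plot_contact_series(series: FrameSeries, path: str, ylabel: Optional[str] = None) -> None:
    n_panels = 1 + (1 if series.per_chain else 0)
    fig, axes = plt.subplots(n_panels, 1, figsize=(6, 2.6 * n_panels), sharex=True, squeeze=False)
    axes[0, 0].plot(series.frame_times, series.total, color="k", lw=1)
    axes[0, 0].set_ylabel(ylabel or series.kind)
    if series.per_chain:
        for c, v in series.per_chain.items():
            axes[1, 0].plot(series.frame_times, v, lw=1, label=c)
        axes[1, 0].legend(frameon=False, fontsize=8)
        axes[1, 0].set_ylabel(f"{series.kind} per chain")
    axes[-1, 0].set_xlabel("time (ns)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_residue_series(series: ResidueSeries, path: str, max_panels: int = 12) -> None:
    labels = series.residue_labels or [str(i) for i in series.residue_indices]
    n = min(series.n_residues, max_panels)
    fig, axes = plt.subplots(n, 1, figsize=(6, 1.4 * n), sharex=True, squeeze=False)
    for k in range(n):
        axes[k, 0].plot(series.frame_times, series.values[k], lw=0.8)
        axes[k, 0].set_ylabel(labels[k], fontsize=7, rotation=0, ha="right")
    axes[-1, 0].set_xlabel("time (ns)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fss_vs_contacts(
    times: np.ndarray,
    fss_counts: np.ndarray,
    contact_counts: np.ndarray,
    path: str,
    label: str = "",
) -> None:
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 4), sharex=True)
    ax1.plot(times, contact_counts, color="tab:blue", lw=1)
    ax1.set_ylabel("side-chain contacts")
    ax2.plot(times, fss_counts, color="tab:red", lw=1)
    ax2.set_ylabel("waters in FSS")
    ax2.set_xlabel("time (ns)")
    if label:
        ax1.set_title(label, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
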