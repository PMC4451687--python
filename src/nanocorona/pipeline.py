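"""End-to-end orchestration: load inputs, run every metric stage over each
replica, tag key residues across replicas, and emit tables + manifest.

Every stage is deterministic given the inputs and configuration; the run
manifest records the configuration hash, package versions and input
checksums so a bundle can be reproduced bit-for-bit.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .contacts import contact_probability, contact_series, contact_surface_area
from .forcefield import energy_series
from .integrity import build_native_contacts, q_series, rmsd_series
from .io import read_structure, read_trajectory, write_table
from .keyres import KeyResidueReport, compose_report, tag_by_energy, tag_by_probability
from .solvation import fss_series
from .structures import Frame, Trajectory

logger = logging.getLogger("nanocorona")

__all__ = ["run", "RunResult"]


@dataclass
class RunResult:
    """Paths and in-memory products of one pipeline run."""

    output_dir: Path
    report: KeyResidueReport
    tables: dict[str, Path] = field(default_factory=dict)
    manifest_path: Optional[Path] = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(cfg: RunConfig) -> RunResult:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level))
    logging.getLogger("MDAnalysis").setLevel(logging.WARNING)
    fh = logging.FileHandler(out / "run.log", mode="w")
    logger.addHandler(fh)
    tables: dict[str, Path] = {}
    try:
        structure, ref_frame = read_structure(
            cfg.structure_path, graphene_resnames=cfg.graphene_resnames
        )
        if cfg.reference_path is not None:
            _, ref_frame = read_structure(cfg.reference_path, graphene_resnames=cfg.graphene_resnames)
        logger.info(
            "topology: %d atoms, %d residues, chains %s",
            structure.n_atoms,
            len(structure.residues),
            structure.chains,
        )
        sheet_sel = structure.group_heavy_atoms("graphene")
        if sheet_sel.size == 0:
            raise ValueError(
                "no graphene atoms found; check selections.graphene_resnames "
                f"(looked for {cfg.graphene_resnames})"
            )
        if cfg.analysis.solvation == "on" and not structure.water_residues():
            raise ValueError("solvation stage enabled but the system contains no water residues")
        table = cfg.lj_table()
        protein_residues = structure.protein_residues()
        eq = cfg.analysis.equilibration_frames

        replica_energy = []
        replica_prob = []
        for ri, tpath in enumerate(cfg.trajectory_paths, 1):
            traj = read_trajectory(
                tpath, structure, graphene_resnames=cfg.graphene_resnames, stride=cfg.analysis.stride
            )
            logger.info("replica %d: %d frames from %s", ri, traj.n_frames, tpath)
            tag = f"rep{ri}"

            cs = contact_series(traj, cfg=cfg.contacts, per_chain=cfg.analysis.per_chain)
            tables[f"contacts_{tag}"] = out / f"contacts_{tag}.tsv"
            write_table(cs, tables[f"contacts_{tag}"])

            es = energy_series(traj, cfg=cfg.energy, table=table)
            replica_energy.append(es)
            tables[f"energy_{tag}"] = out / f"energy_{tag}.tsv"
            write_table(es, tables[f"energy_{tag}"])

            window = (eq, traj.n_frames) if eq else None
            prob = contact_probability(traj, cfg=cfg.contacts, window=window)
            replica_prob.append(prob)
            tables[f"probability_{tag}"] = out / f"probability_{tag}.tsv"
            write_table(prob, tables[f"probability_{tag}"])

            rm = rmsd_series(
                traj,
                ref_frame,
                per_chain=cfg.analysis.per_chain,
                superpose_per_chain=cfg.analysis.superpose_per_chain,
            )
            native = build_native_contacts(
                structure, ref_frame, cfg.analysis.native_cutoff, cfg.analysis.min_separation
            )
            if native.n_pairs:
                qs = q_series(traj, native, per_chain=cfg.analysis.per_chain)
                struct_df = rm.merge(qs, on="time_ns")
            else:
                logger.warning("native-contact set is empty; Q columns omitted")
                struct_df = rm
            tables[f"structure_{tag}"] = out / f"structure_{tag}.tsv"
            write_table(struct_df, tables[f"structure_{tag}"])

            if cfg.analysis.solvation != "off" and structure.water_residues():
                solvable = [r for r in protein_residues if r.sidechain_atom_indices(structure).size]
                fs = fss_series(traj, residues=solvable, cfg=cfg.fss)
                tables[f"fss_{tag}"] = out / f"fss_{tag}.tsv"
                write_table(fs, tables[f"fss_{tag}"])

            if cfg.analysis.surface_area:
                areas = [
                    contact_surface_area(f, structure, cfg=cfg.contacts) for f in traj.frames
                ]
                df = pd.DataFrame({"time_ns": traj.times(), "contact_area_A2": areas})
                tables[f"area_{tag}"] = out / f"area_{tag}.tsv"
                write_table(df, tables[f"area_{tag}"])

        energy_set = tag_by_energy(replica_energy, cfg.tagging)
        # probability rule uses the per-replica mean probability
        prob_mean = {
            int(i): float(np.mean([p.values[k, -1] for p in replica_prob]))
            for k, i in enumerate(replica_prob[0].residue_indices)
        }
        prob_set = tag_by_probability(prob_mean, cfg.tagging)
        info = {r.index: (r.name, r.chain_id) for r in protein_residues}
        w0, w1 = cfg.tagging.resolve_window(replica_energy[0].n_frames)
        energy_means = {
            int(i): [float(s.window_mean(w0, w1)[k]) for s in replica_energy]
            for k, i in enumerate(replica_energy[0].residue_indices)
        }
        report = compose_report(
            energy_set,
            prob_set,
            info,
            mode=cfg.analysis.report_mode,
            cfg=cfg.tagging,
            replica_energy_means=energy_means,
            probabilities=prob_mean,
        )
        tables["key_residues"] = out / "key_residues.tsv"
        if len(report.table):
            write_table(report.table, tables["key_residues"])
        else:
            tables["key_residues"].write_text("no residues satisfied the enabled rules\n")
        (out / "key_residues_summary.txt").write_text(report.summary() + "\n")
        logger.info("tagged %d key residues (%s mode)", len(report.table), report.mode)

        manifest = {
            "package": "nanocorona",
            "version": __version__,
            "config_hash": hashlib.sha256(
                json.dumps(_config_fingerprint(cfg), sort_keys=True).encode()
            ).hexdigest(),
            "inputs": {
                str(p): _sha256(Path(p))
                for p in [cfg.structure_path, *cfg.trajectory_paths]
                + ([cfg.reference_path] if cfg.reference_path else [])
            },
            "outputs": {k: str(v) for k, v in tables.items()},
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        (out / "INCOMPLETE").unlink(missing_ok=True)
        return RunResult(output_dir=out, report=report, tables=tables, manifest_path=manifest_path)
    except Exception:
        (out / "INCOMPLETE").write_text("run aborted before all stages finished\n")
        raise
    finally:
        logger.removeHandler(fh)
        fh.close()


def _config_fingerprint(cfg: RunConfig) -> dict:
    return {
        "structure": str(cfg.structure_path),
        "trajectories": [str(p) for p in cfg.trajectory_paths],
        "reference": str(cfg.reference_path) if cfg.reference_path else None,
        "graphene_resnames": cfg.graphene_resnames,
        "contacts": vars(cfg.contacts) | {"radii": sorted(cfg.contacts.radii.items())},
        "energy": vars(cfg.energy),
        "fss": vars(cfg.fss),
        "tagging": {k: v for k, v in vars(cfg.tagging).items()},
        "analysis": vars(cfg.analysis),
    }
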