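from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from nanocorona.structures import Frame, Structure, Trajectory, build_structure


@pytest.fixture
def tripeptide() -> tuple[Structure, Frame]:
    """Three-residue peptide with backbone + one side-chain atom each."""
    names, resnames, resids, chains = [], [], [], []
    coords = []
    for k, rname in enumerate(["ALA", "SER", "LEU"]):
        for nm, off in [("N", [0.0, 0.0, 0.0]), ("CA", [1.5, 0.0, 0.0]), ("C", [2.2, 1.2, 0.0]), ("O", [2.0, 2.4, 0.3]), ("CB", [2.1, -0.8, 1.2])]:
            names.append(nm)
            resnames.append(rname)
            resids.append(k + 1)
            chains.append("A")
            coords.append(np.array(off) + np.array([3.8 * k, 0.0, 0.0]))
    s = build_structure(names, resnames, resids, chains)
    return s, Frame(np.array(coords))


def make_helix(n_res: int = 14, chain: str = "A", rng=None) -> tuple[Structure, Frame]:
    """Pseudo-helical chain: two heavy atoms per residue on a helix whose
    i → i+4 closest-approach sits just inside 6 Å, so native contacts exist."""
    names, resnames, resids, chains, coords = [], [], [], [], []
    radius, rise, turn = 2.5, 1.4, np.deg2rad(100.0)
    for k in range(n_res):
        ang = k * turn
        ca = np.array([radius * np.cos(ang), radius * np.sin(ang), rise * k])
        cb = ca + np.array([0.8 * np.cos(ang), 0.8 * np.sin(ang), 0.3])
        for nm, p in [("CA", ca), ("CB", cb)]:
            names.append(nm)
            resnames.append("ALA")
            resids.append(k + 1)
            chains.append(chain)
            coords.append(p)
    s = build_structure(names, resnames, resids, chains)
    return s, Frame(np.array(coords))


@pytest.fixture
def helix() -> tuple[Structure, Frame]:
    return make_helix()


def random_two_group_fixture(seed: int, box: bool = False):
    """Randomised pair of point clouds (+ optional box) for oracle checks."""
    rng = np.random.default_rng(seed)
    na, nb = rng.integers(5, 25), rng.integers(10, 60)
    span = 18.0
    xa = rng.uniform(0, span, size=(na, 3))
    xb = rng.uniform(0, span, size=(nb, 3))
    b = np.array([span, span, span]) if box else None
    return xa, xb, b


@pytest.fixture
def small_spec():
    """Reduced synthetic spec for fast unit tests (single adsorbing chain)."""
    from nanocorona.synthetic import ChainPlan, SyntheticSpec

    return SyntheticSpec(
        chains=[
            ChainPlan(
                "A",
                ["ARG", "TYR", "SER", "ASN", "ARG", "ARG", "GLU", "LEU", "TRP", "ARG"],
                [True, True, False, False, True, True, False, False, True, True],
                onset_frame=10,
            )
        ],
        n_frames=30,
        seed=7,
    )
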