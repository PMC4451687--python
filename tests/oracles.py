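"""Independent brute-force / alternative-method oracles used by the tests.

Everything here is deliberately written as the plainest possible double
loop or textbook alternative method, sharing no code path with the package
implementations it checks.
"""
from __future__ import annotations

import numpy as np


def min_image(d: np.ndarray, box) -> np.ndarray:
    if box is None:
        return d
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def brute_contact_count(xa, xb, cutoff, box=None, strict=True) -> int:
    n = 0
    for a in xa:
        for b in xb:
            r = float(np.linalg.norm(min_image(np.asarray(b) - np.asarray(a), box)))
            if (r < cutoff) if strict else (r <= cutoff):
                n += 1
    return n


def brute_lj_energy(xa, xb, sigmas, epsilons, cutoff, box=None) -> float:
    """Sum of 12-6 energies over cross pairs within cutoff; sigmas/epsilons
    are the pre-combined cross parameters, one per atom of xa (kJ/mol)."""
    e = 0.0
    for i, a in enumerate(xa):
        for b in xb:
            r = float(np.linalg.norm(min_image(np.asarray(b) - np.asarray(a), box)))
            if r <= cutoff:
                s6 = (sigmas[i] / r) ** 6
                e += 4.0 * epsilons[i] * (s6 * s6 - s6)
    return e


def lj_direct(r, sigma_i, eps_i, sigma_j, eps_j) -> float:
    """Direct 12-6 evaluation with explicit Lorentz-Berthelot combination,
    written independently of the package formula arrangement."""
    sigma = (sigma_i + sigma_j) / 2.0
    eps = (eps_i * eps_j) ** 0.5
    return 4.0 * eps * ((sigma / r) ** 12 - (sigma / r) ** 6)


def brute_fss_count(side_xyz, water_sites, owners, radius, box=None, inclusive=True) -> int:
    """Exhaustive per-water minimum-distance scan."""
    counted = set()
    for w, site in zip(owners, water_sites):
        dmin = min(
            float(np.linalg.norm(min_image(np.asarray(site) - np.asarray(s), box)))
            for s in side_xyz
        )
        if (dmin <= radius) if inclusive else (dmin < radius):
            counted.add(int(w))
    return len(counted)


def brute_native_pairs(res_heavy_xyz, seq_pos, cutoff, min_sep=3) -> set[tuple[int, int]]:
    """All-residue-pairs scan. res_heavy_xyz: list of (n_i, 3) arrays in
    residue order; seq_pos: list of (chain_id, position) per residue.
    Returns pairs of residue list positions (i < j)."""
    out = set()
    n = len(res_heavy_xyz)
    for i in range(n):
        for j in range(i + 1, n):
            ci, pi = seq_pos[i]
            cj, pj = seq_pos[j]
            if ci == cj and abs(pj - pi) <= min_sep:
                continue
            dmin = min(
                float(np.linalg.norm(b - a))
                for a in res_heavy_xyz[i]
                for b in res_heavy_xyz[j]
            )
            if dmin < cutoff:
                out.add((i, j))
    return out


def quaternion_rmsd(x, y) -> float:
    """Kearsley quaternion-method least-squares RMSD of x onto y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    p = xc + yc  # sums
    m = xc - yc  # differences
    xm, ym, zm = m[:, 0], m[:, 1], m[:, 2]
    xp, yp, zp = p[:, 0], p[:, 1], p[:, 2]
    k = np.empty((4, 4))
    k[0, 0] = np.sum(xm**2 + ym**2 + zm**2)
    k[1, 1] = np.sum(xm**2 + yp**2 + zp**2)
    k[2, 2] = np.sum(xp**2 + ym**2 + zp**2)
    k[3, 3] = np.sum(xp**2 + yp**2 + zm**2)
    k[0, 1] = k[1, 0] = np.sum(yp * zm - ym * zp)
    k[0, 2] = k[2, 0] = np.sum(xm * zp - xp * zm)
    k[0, 3] = k[3, 0] = np.sum(xp * ym - xm * yp)
    k[1, 2] = k[2, 1] = np.sum(xm * ym - xp * yp)
    k[1, 3] = k[3, 1] = np.sum(xm * zm - xp * zp)
    k[2, 3] = k[3, 2] = np.sum(ym * zm - yp * zp)
    lam = np.linalg.eigvalsh(k)[0]
    return float(np.sqrt(max(lam, 0.0) / len(x)))


def mc_sphere_sasa(centers, radii, probe, which, n_points=200_000, seed=0) -> float:
    """Monte-Carlo accessible area of sphere ``which`` in a set of spheres."""
    rng = np.random.default_rng(seed)
    c = np.asarray(centers, dtype=float)
    r = np.asarray(radii, dtype=float) + probe
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    surf = c[which] + r[which] * pts
    accessible = np.ones(n_points, dtype=bool)
    for j in range(len(c)):
        if j == which:
            continue
        accessible &= np.linalg.norm(surf - c[j], axis=1) >= r[j]
    return 4.0 * np.pi * r[which] ** 2 * accessible.mean()
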