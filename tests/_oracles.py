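"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the
implementation it checks: 3D grid quadrature for Gaussian overlap volumes,
an exhaustive rigid-pose grid search for the overlay optimizer, an
all-pairs O(N^2) distance loop for residue contacts, and closed forms for
the solubility-diffusion resistance integral.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

# the Gaussian parameterization under test is part of the contract
from leadscope.shape_screen import P_GAUSS, _alpha


def grid_overlap_volume(centers_a: np.ndarray, centers_b: np.ndarray,
                        radius: float = 1.70, spacing: float = 0.05,
                        pad: float = 4.0) -> float:
    """Overlap volume by direct 3D quadrature of the Gaussian product."""
    al = _alpha(radius)

    def density(points, centers):
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        return (P_GAUSS * np.exp(-al * d2)).sum(1)

    allc = np.vstack([centers_a, centers_b])
    lo, hi = allc.min(0) - pad, allc.max(0) + pad
    axes = [np.arange(l, h + spacing, spacing) for l, h in zip(lo, hi)]
    X, Y = np.meshgrid(axes[0], axes[1], indexing="ij")
    xy = np.stack([X.ravel(), Y.ravel()], 1)
    total = 0.0
    for z in axes[2]:
        pts = np.column_stack([xy, np.full(len(xy), z)])
        total += (density(pts, centers_a) * density(pts, centers_b)).sum()
    return total * spacing ** 3


def pose_grid_best_shape_tanimoto(query: np.ndarray, ref: np.ndarray,
                                  radius: float = 1.70, rot_step: float = 10.0,
                                  t_step: float = 0.1,
                                  t_extent: float = 0.5) -> float:
    """Best shape Tanimoto over an exhaustive rigid-pose grid.

    Euler-angle rotations on a ``rot_step``-degree grid crossed with a
    translation grid of ``t_step`` A within ``+-t_extent`` around the
    centroid-matched position.
    """
    al_q = np.full(len(query), _alpha(radius))
    al_r = np.full(len(ref), _alpha(radius))

    def pair(a, al_a, b, al_b):
        d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
        asum = al_a[:, None] + al_b[None, :]
        return float((P_GAUSS ** 2 * np.exp(-(al_a[:, None] * al_b[None, :] / asum) * d2)
                      * (np.pi / asum) ** 1.5).sum())

    vaa = pair(query, al_q, query, al_q)
    vbb = pair(ref, al_r, ref, al_r)
    qc, rc = query.mean(0), ref.mean(0)
    ts = np.arange(-t_extent, t_extent + 1e-9, t_step)
    T = np.stack(np.meshgrid(ts, ts, ts, indexing="ij"), -1).reshape(-1, 3)
    asum = al_q[:, None] + al_r[None, :]
    k = (al_q[:, None] * al_r[None, :]) / asum
    pref = (P_GAUSS ** 2) * (np.pi / asum) ** 1.5
    angles = np.arange(0.0, 360.0, rot_step)
    betas = np.arange(0.0, 180.0 + 1e-9, rot_step)
    best = -1.0
    for a in angles:
        for b in betas:
            for g in angles:
                R = Rotation.from_euler("zyz", [a, b, g], degrees=True).as_matrix()
                q0 = (query - qc) @ R.T + rc
                diff = q0[:, None, :] - ref[None, :, :]
                d2 = ((diff[:, :, None, :] + T[None, None, :, :]) ** 2).sum(-1)
                vab = (pref[:, :, None] * np.exp(-k[:, :, None] * d2)).sum((0, 1))
                m = (vab / (vaa + vbb - vab)).max()
                if m > best:
                    best = float(m)
    return best


def brute_force_contacts(ligand_xyz: np.ndarray, protein_xyz: np.ndarray,
                         atom_residues, cutoff: float = 4.0) -> frozenset:
    """All-pairs strict-< contact residue set."""
    d = np.linalg.norm(ligand_xyz[:, None, :] - protein_xyz[None, :, :], axis=-1)
    hit = np.any(d < cutoff, axis=0)
    return frozenset(atom_residues[j] for j in np.flatnonzero(hit))


def flat_profile_peff(D_cm2_s: float, span_angstrom: float) -> float:
    """Closed-form permeability of a zero-PMF membrane: D / span."""
    return D_cm2_s / (span_angstrom * 1e-8)


def square_barrier_peff(D_cm2_s: float, span_angstrom: float,
                        width_angstrom: float, height_kcal: float,
                        temperature: float = 300.0) -> float:
    """Closed-form permeability for a square barrier inside the span."""
    kt = 0.0019872041 * temperature
    span_cm = span_angstrom * 1e-8
    w_cm = width_angstrom * 1e-8
    return D_cm2_s / ((span_cm - w_cm) + w_cm * np.exp(height_kcal / kt))
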