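"""Gaussian shape/color overlap scoring and Tanimoto-Combo screening.

Molecular shape is modeled as a sum of atom-centered first-order Gaussians
(Grant-Pickup): each heavy atom contributes ``p * exp(-alpha * r^2)`` with
the width ``alpha`` fixed so the Gaussian integrates to the atom's van der
Waals sphere volume.  By default all heavy atoms share one 1.70 A radius
("radii off" mode).  The overlap volume of two molecules is the sum of all
pairwise Gaussian product integrals, and the shape Tanimoto is

    st(A, B) = V_AB / (V_AA + V_BB - V_AB)

which is 1 exactly for a molecule overlaid on itself.  Pharmacophore color
scoring applies the same Gaussian overlap to typed feature points, counting
only same-kind pairs.  The Tanimoto-Combo score is the sum of shape and
color Tanimotos (range 0-2; 2 = identical shape and feature overlay).  When
either feature set is empty the color term is 0 by convention, so a
featureless molecule has self-similarity 1, not 2.

Overlay optimization seeds local refinement from an inertial-frame
alignment (plus its axis flips) and seeded random rotations, then refines
the rigid-body pose by direct search on the combo score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .chemlib import (FeatureTypingError, Molecule, PharmacophoreFeature,
                      assign_features)

__all__ = [
    "RigidTransform",
    "OverlayResult",
    "ScreenReport",
    "Anchor",
    "gaussian_overlap_volume",
    "shape_tanimoto",
    "color_overlap",
    "color_tanimoto",
    "combo_score",
    "optimize_overlay",
    "screen_library",
    "pharmacophore_point_check",
]

#: Grant-Pickup Gaussian amplitude.
P_GAUSS = 2.7
#: Shared heavy-atom radius (A) in "radii off" mode.
DEFAULT_RADIUS = 1.70
#: Pairs whose Gaussian product falls below this fraction of its peak are skipped.
TRUNCATION = 1e-12


def _alpha(radius: np.ndarray | float) -> np.ndarray | float:
    """Gaussian width such that the atom Gaussian integrates to (4/3) pi r^3."""
    return np.pi * (3.0 * P_GAUSS / (4.0 * np.pi * np.asarray(radius) ** 3)) ** (2.0 / 3.0)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid-body motion ``x -> R @ x + t`` applied to query coordinates."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ np.asarray(self.rotation).T + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        R = np.asarray(self.rotation)
        return RigidTransform(R.T, -R.T @ np.asarray(self.translation))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()


@dataclass
class OverlayResult:
    """Best rigid overlay of a query onto a reference with its scores."""

    transform: RigidTransform
    shape_tanimoto: float
    color_tanimoto: float
    combo: float


@dataclass
class ScreenReport:
    """Ranked screening results plus a score-threshold census."""

    ranked: list[tuple[str, OverlayResult]]
    census: dict[float, int]
    failures: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Gaussian overlap volumes
# ---------------------------------------------------------------------------

def _pair_overlap(xyz_a: np.ndarray, alpha_a: np.ndarray,
                  xyz_b: np.ndarray, alpha_b: np.ndarray) -> float:
    """First-order (pairwise) Gaussian overlap volume between two atom sets."""
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return 0.0
    d2 = np.sum((xyz_a[:, None, :] - xyz_b[None, :, :]) ** 2, axis=-1)
    asum = alpha_a[:, None] + alpha_b[None, :]
    k = alpha_a[:, None] * alpha_b[None, :] / asum
    expo = k * d2
    mask = expo < -np.log(TRUNCATION)
    vol = np.zeros_like(d2)
    vol[mask] = (P_GAUSS * P_GAUSS * np.exp(-expo[mask])
                 * (np.pi / asum[mask]) ** 1.5)
    return float(vol.sum())


def _shape_arrays(mol: Molecule, radius: float) -> tuple[np.ndarray, np.ndarray]:
    xyz = mol.heavy_coords()
    if len(xyz) == 0:
        raise ValueError(f"{mol.name}: no heavy atoms for shape scoring")
    return xyz, np.full(len(xyz), _alpha(radius))


def gaussian_overlap_volume(a: Molecule, b: Molecule,
                            transform: RigidTransform | None = None,
                            radius: float = DEFAULT_RADIUS) -> float:
    """Overlap volume (A^3) between heavy-atom Gaussians of ``a`` and ``b``.

    ``transform`` is applied to ``a`` (the query); hydrogens are excluded.
    """
    xyz_a, al_a = _shape_arrays(a, radius)
    xyz_b, al_b = _shape_arrays(b, radius)
    if transform is not None:
        xyz_a = transform.apply(xyz_a)
    return _pair_overlap(xyz_a, al_a, xyz_b, al_b)


def shape_tanimoto(a: Molecule, b: Molecule,
                   transform: RigidTransform | None = None,
                   radius: float = DEFAULT_RADIUS) -> float:
    """Shape Tanimoto V_AB / (V_AA + V_BB - V_AB) in (0, 1]."""
    xyz_a, al_a = _shape_arrays(a, radius)
    xyz_b, al_b = _shape_arrays(b, radius)
    if transform is not None:
        xyz_a = transform.apply(xyz_a)
    vab = _pair_overlap(xyz_a, al_a, xyz_b, al_b)
    vaa = _pair_overlap(xyz_a, al_a, xyz_a, al_a)
    vbb = _pair_overlap(xyz_b, al_b, xyz_b, al_b)
    return vab / (vaa + vbb - vab)


def _feature_arrays(feats: Sequence[PharmacophoreFeature]):
    xyz = np.array([f.xyz for f in feats], dtype=float).reshape(-1, 3)
    alphas = _alpha(np.array([f.radius for f in feats], dtype=float)) if feats else np.empty(0)
    kinds = np.array([f.kind for f in feats])
    return xyz, np.asarray(alphas), kinds


def color_overlap(feats_a: Sequence[PharmacophoreFeature],
                  feats_b: Sequence[PharmacophoreFeature],
                  transform: RigidTransform | None = None) -> float:
    """Gaussian overlap between same-kind feature points (kind mismatch = 0)."""
    if not feats_a or not feats_b:
        return 0.0
    xyz_a, al_a, kinds_a = _feature_arrays(feats_a)
    xyz_b, al_b, kinds_b = _feature_arrays(feats_b)
    if transform is not None:
        xyz_a = transform.apply(xyz_a)
    total = 0.0
    for kind in set(kinds_a) & set(kinds_b):
        ma, mb = kinds_a == kind, kinds_b == kind
        total += _pair_overlap(xyz_a[ma], al_a[ma], xyz_b[mb], al_b[mb])
    return total


def color_tanimoto(feats_a: Sequence[PharmacophoreFeature],
                   feats_b: Sequence[PharmacophoreFeature],
                   transform: RigidTransform | None = None) -> float:
    """Color Tanimoto in [0, 1]; 0 by convention when either set is empty."""
    if not feats_a or not feats_b:
        return 0.0
    vab = color_overlap(feats_a, feats_b, transform)
    vaa = color_overlap(feats_a, feats_a)
    vbb = color_overlap(feats_b, feats_b)
    denom = vaa + vbb - vab
    return vab / denom if denom > 0 else 0.0


def combo_score(a: Molecule, b: Molecule,
                feats_a: Sequence[PharmacophoreFeature],
                feats_b: Sequence[PharmacophoreFeature],
                transform: RigidTransform | None = None,
                radius: float = DEFAULT_RADIUS) -> tuple[float, float, float]:
    """Return (shape_tanimoto, color_tanimoto, combo) under ``transform``."""
    st = shape_tanimoto(a, b, transform, radius)
    ct = color_tanimoto(feats_a, feats_b, transform)
    return st, ct, st + ct


# ---------------------------------------------------------------------------
# overlay optimization
# ---------------------------------------------------------------------------

def _principal_axes(xyz: np.ndarray) -> np.ndarray:
    """Right-handed principal-axis frame (columns), largest inertia first."""
    centered = xyz - xyz.mean(axis=0)
    cov = centered.T @ centered / max(len(xyz), 1)
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]  # descending eigenvalue order
    if np.linalg.det(v) < 0:
        v[:, 2] *= -1
    return v

_FLIPS = [np.diag(d) for d in
          ([1.0, 1, 1], [1.0, -1, -1], [-1.0, 1, -1], [-1.0, -1, 1])]


def _start_rotations(query_xyz: np.ndarray, ref_xyz: np.ndarray,
                     n_starts: int, seed: int) -> list[np.ndarray]:
    vq, vr = _principal_axes(query_xyz), _principal_axes(ref_xyz)
    # inertial alignment and its axis flips, plus the raw identity pose
    starts = [vr @ f @ vq.T for f in _FLIPS] + [np.eye(3)]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - len(starts))):
        starts.append(Rotation.random(random_state=rng).as_matrix())
    return starts[:n_starts]


def optimize_overlay(query: Molecule, ref: Molecule,
                     n_starts: int = 16, seed: int = 0,
                     feats_query: Sequence[PharmacophoreFeature] | None = None,
                     feats_ref: Sequence[PharmacophoreFeature] | None = None,
                     rules: dict | None = None,
                     radius: float = DEFAULT_RADIUS,
                     maxiter: int = 250) -> OverlayResult:
    """Find the rigid overlay of ``query`` onto ``ref`` maximizing combo.

    Deterministic for fixed ``seed`` and ``n_starts``.  The returned score
    is at least the score of every unrefined starting pose.  Features are
    assigned with the default ruleset when not supplied; pass empty lists
    to score shape only.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if feats_query is None:
        feats_query = assign_features(query, rules)
    if feats_ref is None:
        feats_ref = assign_features(ref, rules)

    q_xyz, q_al = _shape_arrays(query, radius)
    r_xyz, r_al = _shape_arrays(ref, radius)
    fq_xyz, fq_al, fq_kinds = _feature_arrays(list(feats_query))
    fr_xyz, fr_al, fr_kinds = _feature_arrays(list(feats_ref))
    vaa = _pair_overlap(q_xyz, q_al, q_xyz, q_al)
    vbb = _pair_overlap(r_xyz, r_al, r_xyz, r_al)
    has_color = len(fq_xyz) > 0 and len(fr_xyz) > 0
    if has_color:
        caa = color_overlap(list(feats_query), list(feats_query))
        cbb = color_overlap(list(feats_ref), list(feats_ref))
        kind_masks = [(fq_kinds == k, fr_kinds == k)
                      for k in sorted(set(fq_kinds) & set(fr_kinds))]

    q_center = q_xyz.mean(axis=0)
    r_center = r_xyz.mean(axis=0)

    def scores(R: np.ndarray, t: np.ndarray) -> tuple[float, float, float]:
        xa = q_xyz @ R.T + t
        vab = _pair_overlap(xa, q_al, r_xyz, r_al)
        st = vab / (vaa + vbb - vab)
        ct = 0.0
        if has_color:
            fa = fq_xyz @ R.T + t
            cab = 0.0
            for mq, mr in kind_masks:
                cab += _pair_overlap(fa[mq], fq_al[mq], fr_xyz[mr], fr_al[mr])
            denom = caa + cbb - cab
            ct = cab / denom if denom > 0 else 0.0
        return st, ct, st + ct

    def pose(params: np.ndarray, R0: np.ndarray, t0: np.ndarray):
        Rd = Rotation.from_rotvec(params[:3]).as_matrix()
        return Rd @ R0, t0 + params[3:]

    best: tuple[float, float, RigidTransform] | None = None
    for R0 in _start_rotations(q_xyz, r_xyz, n_starts, seed):
        t0 = r_center - R0 @ q_center

        def objective(params: np.ndarray) -> float:
            R, t = pose(params, R0, t0)
            return -scores(R, t)[2]

        res = minimize(objective, np.zeros(6), method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 5e-4, "fatol": 1e-8})
        R, t = pose(res.x, R0, t0)
        st, ct, combo = scores(R, t)
        st0, _, combo0 = scores(R0, t0)
        if combo0 > combo:  # refinement must never lose to its own start
            R, t, st, combo = R0, t0, st0, combo0
        key = (combo, st)
        if best is None or key > (best[0], best[1]):
            best = (combo, st, RigidTransform(R, t))

    combo, st, transform = best
    return OverlayResult(transform=transform, shape_tanimoto=st,
                         color_tanimoto=combo - st, combo=combo)


# ---------------------------------------------------------------------------
# library screening
# ---------------------------------------------------------------------------

def screen_library(template: Molecule, library: Sequence[Molecule],
                   thresholds: Sequence[float] = (1.5, 1.4, 1.3),
                   n_starts: int = 16, seed: int = 0,
                   rules: dict | None = None) -> ScreenReport:
    """Score a library against a template and build a threshold census.

    Molecules whose feature assignment fails are reported in
    ``report.failures`` and skipped, never silently dropped.  Ranking is by
    combo (descending), ties broken by shape Tanimoto, then molecule name.
    """
    if not library:
        raise ValueError("library is empty")
    feats_t = assign_features(template, rules)
    scored: list[tuple[str, OverlayResult]] = []
    failures: list[tuple[str, str]] = []
    for i, mol in enumerate(library):
        try:
            feats_m = assign_features(mol, rules)
        except FeatureTypingError as exc:
            failures.append((mol.name, str(exc)))
            continue
        result = optimize_overlay(mol, template, n_starts=n_starts,
                                  seed=seed + i,
                                  feats_query=feats_m, feats_ref=feats_t,
                                  rules=rules)
        scored.append((mol.name, result))
    scored.sort(key=lambda item: (-item[1].combo, -item[1].shape_tanimoto, item[0]))
    census = {float(th): sum(1 for _, r in scored if r.combo > th)
              for th in thresholds}
    return ScreenReport(ranked=scored, census=census, failures=failures)


# ---------------------------------------------------------------------------
# pharmacophore anchor check (programmatic surrogate of visual inspection)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Anchor:
    """A required pharmacophore point in the template frame."""

    name: str
    kind: str
    position: tuple[float, float, float]


def pharmacophore_point_check(overlay: OverlayResult,
                              feats_query: Sequence[PharmacophoreFeature],
                              anchors: Sequence[Anchor],
                              tolerance: float = 1.5) -> dict[str, bool]:
    """Check whether the overlaid query places same-kind features on anchors.

    For each anchor, reports True when the query (after applying the overlay
    transform) has a feature of the anchor's kind within ``tolerance`` A of
    the anchor position.  Anchors referencing kinds the query lacks are
    reported unmatched, not raised.
    """
    report: dict[str, bool] = {}
    for anchor in anchors:
        matched = False
        target = np.asarray(anchor.position, dtype=float)
        for f in feats_query:
            if f.kind != anchor.kind:
                continue
            pos = overlay.transform.apply(f.xyz[None, :])[0]
            if np.linalg.norm(pos - target) < tolerance:
                matched = True
                break
        report[anchor.name] = matched
    return report
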