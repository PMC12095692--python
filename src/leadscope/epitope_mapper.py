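"""Binding-epitope detection from free-ligand-diffusion trajectories.

A ligand diffusing around a protein in an unbiased simulation samples
association and dissociation events.  This module identifies where it
binds:

1. per-frame residue *contact fingerprints* (any ligand heavy atom within
   a cutoff, default 4 A strict, of any residue heavy atom);
2. a *bound-frame filter* (at least ``min_residues`` distinct residues in
   contact, default 5), separating genuine binding from grazing contacts;
3. a symmetry-aware ligand heavy-atom *density grid* after per-frame
   least-squares superposition of the protein onto a reference;
4. agglomerative *clustering* of the bound-frame fingerprints (Jaccard
   distance, average linkage) into binding epitopes;
5. an *occupancy report*: percent of all trajectory frames per epitope,
   per-residue contact frequencies, and flags for user-designated hot-spot
   residues (e.g. the tryptophans essential for tetramerization).

Trajectories are multi-model PDB files (plain text) read with MDAnalysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

__all__ = [
    "Trajectory",
    "ContactFingerprint",
    "DensityGrid",
    "EpitopeCluster",
    "EpitopeReport",
    "load_trajectory",
    "contact_fingerprint",
    "trajectory_fingerprints",
    "filter_bound_frames",
    "superpose",
    "density_grid",
    "cluster_fingerprints",
    "epitope_report",
    "write_dx",
]

ResidueKey = tuple[str, int]


@dataclass
class Trajectory:
    """Per-frame ligand and protein heavy-atom coordinates.

    ``ligand_coords``: (n_frames, n_ligand_atoms, 3) A.
    ``protein_coords``: (n_frames, n_protein_atoms, 3) A.
    ``atom_residues``: residue key (chain, resid) per protein atom.
    ``ca_mask``: boolean mask of protein atoms used for superposition.
    """

    ligand_coords: np.ndarray
    protein_coords: np.ndarray
    atom_residues: list[ResidueKey]
    ca_mask: np.ndarray
    frame_interval_ps: float = 100.0

    def __post_init__(self) -> None:
        self.ligand_coords = np.asarray(self.ligand_coords, dtype=float)
        self.protein_coords = np.asarray(self.protein_coords, dtype=float)
        if self.ligand_coords.shape[0] != self.protein_coords.shape[0]:
            raise ValueError("ligand/protein frame counts differ")
        if self.protein_coords.shape[1] != len(self.atom_residues):
            raise ValueError("protein atom count does not match residue labels")
        for arr in (self.ligand_coords, self.protein_coords):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite coordinates in trajectory")
        self.ca_mask = np.asarray(self.ca_mask, dtype=bool)

    @property
    def n_frames(self) -> int:
        return int(self.ligand_coords.shape[0])

    @property
    def residues(self) -> list[ResidueKey]:
        seen: dict[ResidueKey, None] = {}
        for key in self.atom_residues:
            seen.setdefault(key, None)
        return list(seen)


@dataclass(frozen=True)
class ContactFingerprint:
    """Residues contacted by the ligand in one frame."""

    frame: int
    residues: frozenset[ResidueKey]


@dataclass
class DensityGrid:
    """Voxelized ligand heavy-atom counts on a regular grid."""

    origin: np.ndarray      # (3,) A, corner of voxel (0,0,0)
    spacing: float          # A
    counts: np.ndarray      # (nx, ny, nz) integer counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EpitopeCluster:
    frames: list[int]
    occupancy_pct: float
    residue_frequency: dict[ResidueKey, float]
    hot_spot_residues: list[ResidueKey] = field(default_factory=list)


@dataclass
class EpitopeReport:
    clusters: list[EpitopeCluster]
    n_frames_total: int
    n_bound: int


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def load_trajectory(path, ligand_resname: str = "LIG",
                    frame_interval_ps: float = 100.0) -> Trajectory:
    """Read a multi-model PDB trajectory (MODEL/ENDMDL records).

    Hydrogens are dropped on both sides; the ligand is selected by residue
    name; alpha-carbons (atom name CA) define the superposition mask.
    """
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        lig = u.select_atoms(f"resname {ligand_resname} and not name H*")
        prot = u.select_atoms(f"not resname {ligand_resname} and not name H*")
        if lig.n_atoms == 0:
            raise ValueError(f"no ligand atoms with resname {ligand_resname!r}")
        if prot.n_atoms == 0:
            raise ValueError("no protein atoms in trajectory")
        chains = [getattr(a, "chainID", "") or a.segid or "A" for a in prot]
        atom_residues = [(c, int(a.resid)) for c, a in zip(chains, prot)]
        ca_mask = np.array([a.name == "CA" for a in prot], dtype=bool)
        lig_frames, prot_frames = [], []
        for _ in u.trajectory:
            lig_frames.append(lig.positions.copy())
            prot_frames.append(prot.positions.copy())
    return Trajectory(
        ligand_coords=np.array(lig_frames),
        protein_coords=np.array(prot_frames),
        atom_residues=atom_residues,
        ca_mask=ca_mask,
        frame_interval_ps=frame_interval_ps,
    )


# ---------------------------------------------------------------------------
# contacts and bound-frame filtering
# ---------------------------------------------------------------------------

def contact_fingerprint(ligand_xyz: np.ndarray, protein_xyz: np.ndarray,
                        atom_residues: Sequence[ResidueKey],
                        cutoff: float = 4.0, frame: int = 0) -> ContactFingerprint:
    """Residues with any heavy-atom pair strictly closer than ``cutoff`` A."""
    lig = np.asarray(ligand_xyz, dtype=float)
    prot = np.asarray(protein_xyz, dtype=float)
    tree = cKDTree(prot)
    contacted: set[ResidueKey] = set()
    for neighbors, point in zip(tree.query_ball_point(lig, r=cutoff), lig):
        for j in neighbors:
            if np.linalg.norm(prot[j] - point) < cutoff:  # enforce strict <
                contacted.add(atom_residues[j])
    return ContactFingerprint(frame=frame, residues=frozenset(contacted))


def trajectory_fingerprints(traj: Trajectory,
                            cutoff: float = 4.0) -> list[ContactFingerprint]:
    """Contact fingerprint for every frame of a trajectory."""
    return [
        contact_fingerprint(traj.ligand_coords[i], traj.protein_coords[i],
                            traj.atom_residues, cutoff=cutoff, frame=i)
        for i in range(traj.n_frames)
    ]


def filter_bound_frames(fingerprints: Sequence[ContactFingerprint],
                        min_residues: int = 5) -> list[int]:
    """Frames whose fingerprint covers at least ``min_residues`` residues."""
    return [fp.frame for fp in fingerprints if len(fp.residues) >= min_residues]


# ---------------------------------------------------------------------------
# superposition and density grid
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit of ``mobile`` onto ``reference`` (Kabsch).

    Returns (R, t) with ``R @ x + t`` mapping mobile coordinates onto the
    reference frame.  Degenerate inputs (< 3 atoms, or rank-deficient)
    raise ValueError.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("superposition needs >= 3 matched atoms")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    import warnings

    with warnings.catch_warnings():
        # rank deficiency is detected and raised explicitly below
        warnings.simplefilter("ignore")
        rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc)
    if np.linalg.matrix_rank(np.cov((mobile - mc).T)) < 2:
        raise ValueError("degenerate coordinates: superposition is singular")
    R = rot.as_matrix()
    return R, rc - R @ mc


def _fold_points(points: np.ndarray,
                 symmetry_ops: Sequence[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Map each point to its canonical symmetry image.

    The canonical image is the lexicographically smallest coordinate tuple
    over all operator images (identity is always included), so each point
    contributes exactly once and total counts are conserved.
    """
    ops = [(np.eye(3), np.zeros(3))]
    ops += [(np.asarray(R, float), np.asarray(t, float)) for R, t in symmetry_ops]
    images = np.stack([points @ R.T + t for R, t in ops])  # (n_ops, n, 3)
    keys = np.round(images, 6)
    order = np.lexsort((keys[..., 2], keys[..., 1], keys[..., 0]), axis=0)[0]
    return images[order, np.arange(points.shape[0])]


def density_grid(traj: Trajectory, bound_frames: Sequence[int],
                 spacing: float = 1.0,
                 reference: np.ndarray | None = None,
                 symmetry_ops: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
                 ) -> DensityGrid:
    """Accumulate superposed ligand heavy-atom positions on a voxel grid.

    Each bound frame's protein (alpha-carbon atoms) is least-squares fitted
    to the reference (default: first-frame protein), the fit applied to the
    ligand atoms, and voxel counts accumulated.  ``symmetry_ops`` — rigid
    (R, t) operators of the protein's internal symmetry, expressed in the
    reference frame — fold equivalent positions onto one asymmetric unit.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    fit_mask = traj.ca_mask if traj.ca_mask.any() else np.ones(
        traj.protein_coords.shape[1], dtype=bool)
    ref = (traj.protein_coords[0] if reference is None else
           np.asarray(reference, dtype=float))
    ref_fit = ref[fit_mask]
    points = []
    for i in bound_frames:
        R, t = superpose(traj.protein_coords[i][fit_mask], ref_fit)
        points.append(traj.ligand_coords[i] @ R.T + t)
    if points:
        pts = np.concatenate(points)
    else:
        pts = np.empty((0, 3))
    if symmetry_ops:
        pts = _fold_points(pts, symmetry_ops)
    if len(pts) == 0:
        return DensityGrid(origin=np.zeros(3), spacing=spacing,
                           counts=np.zeros((1, 1, 1), dtype=int))
    # snap away sub-1e-6 superposition noise so voxel-corner points bin stably
    pts = np.round(pts, 6)
    origin = np.floor(pts.min(axis=0) / spacing) * spacing
    idx = np.floor((pts - origin) / spacing).astype(int)
    shape = idx.max(axis=0) + 1
    counts = np.zeros(shape, dtype=int)
    np.add.at(counts, tuple(idx.T), 1)
    return DensityGrid(origin=origin, spacing=spacing, counts=counts)


def write_dx(grid: DensityGrid, path) -> None:
    """Write a density grid in OpenDX scalar-field format."""
    nx, ny, nz = grid.counts.shape
    sp = grid.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*grid.origin))
        fh.write(f"delta {sp:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {sp:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {sp:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n")
        flat = grid.counts.ravel(order="C").astype(float)
        for start in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.1f}" for v in flat[start:start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


# ---------------------------------------------------------------------------
# fingerprint clustering and occupancy report
# ---------------------------------------------------------------------------

def canonicalize_fingerprints(fps: Sequence[ContactFingerprint],
                              chain_map: dict[str, str]) -> list[ContactFingerprint]:
    """Map symmetry-equivalent chains onto one protomer before clustering."""
    return [
        ContactFingerprint(
            frame=fp.frame,
            residues=frozenset((chain_map.get(c, c), r) for c, r in fp.residues),
        )
        for fp in fps
    ]


def cluster_fingerprints(fps: Sequence[ContactFingerprint],
                         linkage: str = "average",
                         distance_metric: str = "jaccard",
                         cut: float = 0.7) -> list[list[int]]:
    """Agglomerative clustering of bound-frame fingerprints.

    Fingerprints are encoded as binary residue vectors; pairwise distances
    (default Jaccard) feed average-linkage clustering cut at ``cut``.
    Returns disjoint clusters as lists of indices into ``fps``, ordered by
    size (largest first), deterministic.
    """
    if len(fps) == 0:
        return []
    if len(fps) == 1:
        return [[0]]
    residues = sorted({r for fp in fps for r in fp.residues})
    if not residues:
        return [list(range(len(fps)))]
    index = {r: i for i, r in enumerate(residues)}
    matrix = np.zeros((len(fps), len(residues)), dtype=bool)
    for i, fp in enumerate(fps):
        for r in fp.residues:
            matrix[i, index[r]] = True
    dists = pdist(matrix, metric=distance_metric)
    if np.all(dists == 0):
        return [list(range(len(fps)))]
    Z = scipy_linkage(dists, method=linkage)
    labels = fcluster(Z, t=cut, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    return sorted(clusters.values(), key=lambda c: (-len(c), c[0]))


def epitope_report(n_frames_total: int,
                   fps: Sequence[ContactFingerprint],
                   clusters: Sequence[Sequence[int]],
                   hot_spots: Sequence[ResidueKey] | None = None,
                   denominator: str = "all") -> EpitopeReport:
    """Occupancy-ranked epitope summary.

    Occupancy is the percentage of *all* trajectory frames in a cluster
    (``denominator="all"``, the default, so occupancies read as fractions
    of simulation time) or of bound frames only (``denominator="bound"``).
    Hot-spot residues contacted by a cluster are flagged.
    """
    if denominator not in ("all", "bound"):
        raise ValueError("denominator must be 'all' or 'bound'")
    n_bound = sum(len(c) for c in clusters)
    denom = n_frames_total if denominator == "all" else max(n_bound, 1)
    hot = set(hot_spots or [])
    out: list[EpitopeCluster] = []
    for members in clusters:
        freq: dict[ResidueKey, int] = {}
        for i in members:
            for r in fps[i].residues:
                freq[r] = freq.get(r, 0) + 1
        n = len(members)
        residue_freq = {r: c / n for r, c in sorted(freq.items())}
        out.append(EpitopeCluster(
            frames=sorted(fps[i].frame for i in members),
            occupancy_pct=100.0 * n / denom,
            residue_frequency=residue_freq,
            hot_spot_residues=sorted(r for r in residue_freq if r in hot),
        ))
    out.sort(key=lambda c: (-c.occupancy_pct, c.frames[0] if c.frames else -1))
    return EpitopeReport(clusters=out, n_frames_total=n_frames_total,
                         n_bound=n_bound)
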