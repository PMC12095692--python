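"""Seeded generators for every input type of the pipeline.

Each generator plants known truth values (an IC50, a K_D, a Tm, a pKa,
epitope occupancies, a calibration line...) into data with the statistical
structure the corresponding stage assumes, so the full pipeline is testable
without any external data.  All generators draw from one explicit
``numpy.random.default_rng(seed)`` stream and are byte-identical under a
fixed seed; every generator records its planted truths in a manifest
(returned as a dict, written as JSON next to the data when an output path
is given).

Default parameters mirror the assay designs of the study this pipeline
supports: 8-point [1, 450] uM triplicate dose-response curves normalized to
vehicle, 16-point 1:1 serial-dilution MST titrations with 100 nM labeled
target, 20-95 C melting ramps read out as the F350/F330 ratio, pH 2-13
chemical-shift titrations in 0.5 steps, free-ligand-diffusion trajectories
around a mock helical bundle, and Gaussian barrier/well PMF profiles with
nine-compound calibration sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assay_fits import bound_fraction, four_pl, henderson_hasselbalch
from .chemlib import Molecule, write_sdf
from .epitope_mapper import ResidueKey, Trajectory

__all__ = [
    "example_template",
    "gen_molecule_library",
    "gen_dose_response",
    "gen_mst_titration",
    "gen_melting_curve",
    "gen_ph_titration",
    "gen_std_intensities",
    "build_helix_bundle",
    "gen_trajectory",
    "gen_pmf_profile",
    "gen_calibration_set",
    "write_manifest",
]


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Write a planted-truth manifest as deterministic JSON."""
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _maybe_write_csv(df: pd.DataFrame, out: str | Path | None,
                     manifest: dict) -> None:
    if out is not None:
        out = Path(out)
        df.to_csv(out, index=False, float_format="%.10g")
        write_manifest(manifest, out.with_suffix(".manifest.json"))


# ---------------------------------------------------------------------------
# molecules
# ---------------------------------------------------------------------------

def example_template(seed: int = 61453) -> Molecule:
    """A small 3D template molecule (benzodioxole-acetic-acid scaffold).

    Built deterministically from SMILES with an ETKDG embedding; carries a
    carboxylic acid (anion feature at pH 7.4), two ring features, acceptors
    and a hydrophobic patch -- enough to exercise every scoring kind.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles("OC(=O)Cc1ccc2OCOc2c1")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError("template embedding failed")
    AllChem.MMFFOptimizeMolecule(mol)
    mol.SetProp("_Name", "template")
    return Molecule.from_rdkit(mol)


def gen_molecule_library(template: Molecule | None = None, n: int = 20,
                         noise_levels: Sequence[float] | None = None,
                         seed: int = 0,
                         out_sdf: str | Path | None = None
                         ) -> tuple[list[Molecule], dict]:
    """Perturbed copies of a template with increasing coordinate noise.

    Member ``k`` is the template under a random rigid motion plus isotropic
    Gaussian coordinate jitter of magnitude ``noise_levels[k]`` (A), so the
    expected combo score against the template decreases with the noise
    level and is exactly 2 at noise 0.  The manifest records the per-member
    perturbation magnitude.
    """
    from scipy.spatial.transform import Rotation

    if n < 1:
        raise ValueError("n must be >= 1")
    if template is None:
        template = example_template()
    if noise_levels is None:
        noise_levels = np.linspace(0.0, 1.0, n)
    noise_levels = np.asarray(list(noise_levels), dtype=float)
    if len(noise_levels) != n:
        raise ValueError("noise_levels length must equal n")
    rng = np.random.default_rng(seed)
    members: list[Molecule] = []
    for k in range(n):
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-5.0, 5.0, size=3)
        coords = template.coords @ R.T + t
        if noise_levels[k] > 0:
            coords = coords + rng.normal(0.0, noise_levels[k], size=coords.shape)
        members.append(Molecule(
            name=f"analog_{k:03d}",
            elements=list(template.elements),
            coords=coords,
            formal_charges=list(template.formal_charges),
            bonds=list(template.bonds),
        ))
    manifest = {
        "kind": "molecule_library",
        "seed": int(seed),
        "template": template.name,
        "members": [
            {"name": m.name, "noise_angstrom": float(noise_levels[k])}
            for k, m in enumerate(members)
        ],
    }
    if out_sdf is not None:
        out_sdf = Path(out_sdf)
        write_sdf(members, out_sdf)
        write_manifest(manifest, out_sdf.with_suffix(".manifest.json"))
    return members, manifest


# ---------------------------------------------------------------------------
# titration-style assays
# ---------------------------------------------------------------------------

def gen_dose_response(ic50: float = 33.0, hill: float = 1.2, top: float = 1.0,
                      bottom: float = 0.05,
                      concentrations: Sequence[float] | None = None,
                      replicates: int = 3, noise_sd: float = 0.03,
                      seed: int = 0, out: str | Path | None = None
                      ) -> tuple[pd.DataFrame, dict]:
    """4PL viability curve + Gaussian noise; vehicle-normalized scale.

    Default design: 8 log-spaced concentrations in [1, 450] uM, triplicate.
    """
    if concentrations is None:
        concentrations = np.logspace(np.log10(1.0), np.log10(450.0), 8)
    x = np.asarray(list(concentrations), dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    clean = four_pl(x, np.log10(ic50), hill, top, bottom)
    y = clean[:, None] + rng.normal(0.0, noise_sd, size=(len(x), replicates))
    df = pd.DataFrame({"concentration_uM": x})
    for r in range(replicates):
        df[f"viability_rep{r + 1}"] = y[:, r]
    manifest = {"kind": "dose_response", "seed": int(seed),
                "ic50_uM": float(ic50), "hill": float(hill),
                "top": float(top), "bottom": float(bottom),
                "noise_sd": float(noise_sd), "replicates": int(replicates)}
    _maybe_write_csv(df, out, manifest)
    return df, manifest


def gen_mst_titration(kd: float = 39.0, target_conc_nM: float = 100.0,
                      top_conc: float = 1000.0, n_points: int = 16,
                      f_free: float = 850.0, amplitude: float = 10.0,
                      noise_sd: float = 0.2, seed: int = 0,
                      out: str | Path | None = None,
                      replicates: int = 3) -> tuple[pd.DataFrame, dict]:
    """1:1 serial-dilution MST titration from the exact quadratic isotherm.

    Default design: 16 concentrations by 1:1 dilution from 1 mM (1000 uM),
    100 nM labeled target, measured in triplicate;
    Fnorm = f_free + amplitude * bound_fraction.
    """
    if n_points < 8:
        raise ValueError("need at least 8 titration points")
    rng = np.random.default_rng(seed)
    L = top_conc / (2.0 ** np.arange(n_points))[::-1]  # ascending, uM
    fb = bound_fraction(L, kd, target_conc_nM * 1e-3)
    clean = f_free + amplitude * fb
    y = clean[:, None] + rng.normal(0.0, noise_sd, size=(n_points, replicates))
    df = pd.DataFrame({"ligand_uM": L})
    for r in range(replicates):
        df[f"fnorm_rep{r + 1}"] = y[:, r]
    manifest = {"kind": "mst_titration", "seed": int(seed), "kd_uM": float(kd),
                "target_conc_nM": float(target_conc_nM),
                "top_conc_uM": float(top_conc), "f_free": float(f_free),
                "amplitude": float(amplitude), "noise_sd": float(noise_sd)}
    _maybe_write_csv(df, out, manifest)
    return df, manifest


def gen_melting_curve(tm: float = 74.5, width: float = 2.0,
                      ratio_baseline: float = 0.85, amplitude: float = 0.15,
                      baseline_slope: float = 0.0005,
                      t_range: tuple[float, float] = (20.0, 95.0),
                      step: float = 0.5, f330_level: float = 1000.0,
                      noise_sd: float = 0.0, seed: int = 0,
                      out: str | Path | None = None) -> tuple[pd.DataFrame, dict]:
    """Two-state melting curve reported as F330/F350 channels.

    The F350/F330 ratio is a logistic transition on a linear baseline;
    ``width`` is the full width at half maximum of the first-derivative
    peak in degrees C (the temperature span the unfolding transition
    visibly occupies), so the logistic scale is ``width / (2 ln(3+2*sqrt(2)))``.
    Because an additive linear baseline does not move the extremum of the
    logistic derivative, the planted ``tm`` is exactly the first-derivative
    extremum of the clean ratio.  ``noise_sd`` is multiplicative per
    channel (0.005 = 0.5%).  ``amplitude=0`` produces a transition-free
    curve.
    """
    T = np.arange(t_range[0], t_range[1] + 0.5 * step, step)
    rng = np.random.default_rng(seed)
    scale = width / (2.0 * np.log(3.0 + 2.0 * np.sqrt(2.0)))  # FWHM -> logistic
    u = 1.0 / (1.0 + np.exp(-(T - tm) / scale))
    ratio = ratio_baseline + baseline_slope * (T - T[0]) + amplitude * u
    f330 = np.full_like(T, f330_level)
    f350 = ratio * f330
    if noise_sd > 0:
        f330 = f330 * (1.0 + rng.normal(0.0, noise_sd, size=T.shape))
        f350 = f350 * (1.0 + rng.normal(0.0, noise_sd, size=T.shape))
    df = pd.DataFrame({"temperature_C": T, "F330": f330, "F350": f350})
    manifest = {"kind": "melting_curve", "seed": int(seed), "tm_C": float(tm),
                "width_C": float(width), "amplitude": float(amplitude),
                "baseline_slope": float(baseline_slope),
                "noise_sd": float(noise_sd)}
    _maybe_write_csv(df, out, manifest)
    return df, manifest


def gen_ph_titration(pka: float = 6.69, delta_acid: float = 1.20,
                     delta_base: float = 0.95,
                     ph_grid: Sequence[float] | None = None,
                     noise_sd: float = 0.0, seed: int = 0,
                     out: str | Path | None = None) -> tuple[pd.DataFrame, dict]:
    """Henderson-Hasselbalch chemical-shift titration, pH 2-13 in 0.5 steps."""
    if ph_grid is None:
        ph_grid = np.arange(2.0, 13.0 + 0.25, 0.5)
    ph = np.asarray(list(ph_grid), dtype=float)
    rng = np.random.default_rng(seed)
    delta = henderson_hasselbalch(ph, pka, delta_acid, delta_base)
    delta = delta + rng.normal(0.0, noise_sd, size=ph.shape)
    df = pd.DataFrame({"pH": ph, "shift_ppm": delta})
    manifest = {"kind": "ph_titration", "seed": int(seed), "pka": float(pka),
                "delta_acid_ppm": float(delta_acid),
                "delta_base_ppm": float(delta_base), "noise_sd": float(noise_sd)}
    _maybe_write_csv(df, out, manifest)
    return df, manifest


def gen_std_intensities(effects: Sequence[float] = (0.41, 0.66, 0.91),
                        i_0: float = 1000.0, noise_sd: float = 0.0,
                        seed: int = 0, out: str | Path | None = None
                        ) -> tuple[pd.DataFrame, dict]:
    """Per-proton on/off-resonance intensity pairs with planted effects."""
    rng = np.random.default_rng(seed)
    effects = np.asarray(list(effects), dtype=float)
    i_sat = effects * i_0 * (1.0 + rng.normal(0.0, noise_sd, size=effects.shape))
    df = pd.DataFrame({
        "proton": [f"H{k + 1}" for k in range(len(effects))],
        "i_sat": i_sat,
        "i_0": np.full_like(effects, i_0),
    })
    manifest = {"kind": "std_intensities", "seed": int(seed),
                "effects": [float(e) for e in effects],
                "noise_sd": float(noise_sd)}
    _maybe_write_csv(df, out, manifest)
    return df, manifest


# ---------------------------------------------------------------------------
# mock protein and free-ligand-diffusion trajectory
# ---------------------------------------------------------------------------

@dataclass
class MockBundle:
    """Parametric four-helix bundle: CA + pseudo-side-chain (CB) per residue."""

    coords: np.ndarray            # (n_atoms, 3)
    atom_residues: list[ResidueKey]
    atom_names: list[str]
    ca_mask: np.ndarray


def build_helix_bundle(n_res: int = 18, bundle_radius: float = 8.0,
                       helix_radius: float = 2.3, rise: float = 1.5,
                       twist_deg: float = 100.0,
                       chains: str = "ABCD") -> MockBundle:
    """Build a C_n-symmetric parallel helix bundle (one helix per chain).

    Helix 0 runs along z; helix k is helix 0 rotated by 360/len(chains)
    degrees about z, so the bundle carries exact internal rotational
    symmetry (the 2-fold operator maps chain A onto C and B onto D for the
    default four chains).
    """
    coords, atom_residues, atom_names, ca_flags = [], [], [], []
    twist = np.deg2rad(twist_deg)
    for k, chain in enumerate(chains):
        phi = 2.0 * np.pi * k / len(chains)
        Rz = np.array([[np.cos(phi), -np.sin(phi), 0.0],
                       [np.sin(phi), np.cos(phi), 0.0],
                       [0.0, 0.0, 1.0]])
        for i in range(n_res):
            theta = twist * i
            ca_local = np.array([bundle_radius + helix_radius * np.cos(theta),
                                 helix_radius * np.sin(theta), rise * i])
            # pseudo side chain points radially away from the helix axis
            out_dir = np.array([np.cos(theta), np.sin(theta), 0.0])
            cb_local = ca_local + 1.8 * out_dir
            for name, pos in (("CA", ca_local), ("CB", cb_local)):
                coords.append(Rz @ pos)
                atom_residues.append((chain, i + 1))
                atom_names.append(name)
                ca_flags.append(name == "CA")
    return MockBundle(coords=np.array(coords), atom_residues=atom_residues,
                      atom_names=atom_names, ca_mask=np.array(ca_flags))


def _brute_contact_count(lig: np.ndarray, prot: np.ndarray,
                         atom_residues: Sequence[ResidueKey],
                         cutoff: float = 4.0) -> set[ResidueKey]:
    d = np.linalg.norm(lig[:, None, :] - prot[None, :, :], axis=-1)
    hit = np.any(d < cutoff, axis=0)
    return {atom_residues[j] for j in np.flatnonzero(hit)}


def gen_trajectory(n_frames: int = 1000,
                   epitope_specs: Sequence[tuple[Sequence[ResidueKey], float]] | None = None,
                   mock_protein: MockBundle | None = None,
                   seed: int = 0, jitter: float = 0.15,
                   out_pdb: str | Path | None = None,
                   ligand_resname: str = "LIG",
                   frame_interval_ps: float = 100.0
                   ) -> tuple[Trajectory, dict]:
    """Free-ligand-diffusion trajectory with planted contact epitopes.

    For each ``(residue_set, fraction)`` spec the ligand is parked against
    that residue set (one ligand heavy atom ~1 A outside each residue's
    side-chain atom, rigid-body jittered per frame) in exactly
    ``round(fraction * n_frames)`` frames; remaining frames place the
    ligand far from the protein (zero contacts).  The construction is
    verified frame by frame (bound frames contact >= 5 residues including
    the full planted set; unbound frames contact < 5) before returning.
    The manifest records the planted residue sets, the per-epitope frame
    indices and the resulting occupancies.
    """
    if mock_protein is None:
        mock_protein = build_helix_bundle()
    if epitope_specs is None:
        epitope_specs = [
            ([("A", i) for i in range(5, 10)], 0.132),
            ([("C", i) for i in range(10, 15)], 0.101),
        ]
    sets = [list(rs) for rs, _ in epitope_specs]
    fractions = [float(f) for _, f in epitope_specs]
    if sum(fractions) > 1.0 + 1e-9:
        raise ValueError("epitope fractions must sum to at most 1")
    for a in range(len(sets)):
        for b in range(a + 1, len(sets)):
            if set(sets[a]) & set(sets[b]):
                raise ValueError("epitope residue sets must be disjoint")

    prot = mock_protein.coords
    res_index: dict[ResidueKey, list[int]] = {}
    for j, key in enumerate(mock_protein.atom_residues):
        res_index.setdefault(key, []).append(j)
    for rs in sets:
        missing = [r for r in rs if r not in res_index]
        if missing:
            raise ValueError(f"epitope residues not in mock protein: {missing}")
        if len(rs) < 5:
            raise ValueError("each epitope needs >= 5 residues to count as bound")

    center = prot.mean(axis=0)
    rng = np.random.default_rng(seed)
    counts = [int(round(f * n_frames)) for f in fractions]
    if sum(counts) > n_frames:
        raise ValueError("epitope fractions leave no room for unbound frames")
    order = rng.permutation(n_frames)
    assignment = np.full(n_frames, -1, dtype=int)  # -1 = unbound
    pos = 0
    for e, c in enumerate(counts):
        assignment[order[pos:pos + c]] = e
        pos += c

    # one ligand heavy atom parked just outside each planted residue's CB
    anchors = []
    for rs in sets:
        pts = []
        for key in rs:
            cb = [j for j in res_index[key] if mock_protein.atom_names[j] == "CB"]
            j = cb[0] if cb else res_index[key][0]
            p = prot[j]
            outward = (p - center) / np.linalg.norm(p - center)
            pts.append(p + 1.0 * outward)
        anchors.append(np.array(pts))

    n_lig = max((len(a) for a in anchors), default=5)
    radius_far = np.max(np.linalg.norm(prot - center, axis=1)) + 25.0
    lig_frames = np.empty((n_frames, n_lig, 3))
    for i in range(n_frames):
        e = assignment[i]
        if e >= 0:
            base = anchors[e]
            if len(base) < n_lig:  # pad by repeating the last anchor point
                base = np.vstack([base, np.repeat(base[-1:], n_lig - len(base), axis=0)])
            lig_frames[i] = base + rng.normal(0.0, jitter, size=3)
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            far = center + radius_far * direction
            spread = rng.normal(0.0, 1.0, size=(n_lig, 3))
            lig_frames[i] = far + spread

    # verify the construction against a brute-force contact count
    for i in range(n_frames):
        contacted = _brute_contact_count(lig_frames[i], prot,
                                         mock_protein.atom_residues)
        e = assignment[i]
        if e >= 0:
            if len(contacted) < 5 or not set(sets[e]) <= contacted:
                raise RuntimeError(f"bound frame {i} does not realize its epitope")
            for other in range(len(sets)):
                if other != e and set(sets[other]) & contacted:
                    raise RuntimeError(f"frame {i} bleeds into another epitope")
        elif len(contacted) >= 5:
            raise RuntimeError(f"unbound frame {i} has too many contacts")

    traj = Trajectory(
        ligand_coords=lig_frames,
        protein_coords=np.broadcast_to(prot, (n_frames,) + prot.shape).copy(),
        atom_residues=list(mock_protein.atom_residues),
        ca_mask=mock_protein.ca_mask.copy(),
        frame_interval_ps=frame_interval_ps,
    )
    manifest = {
        "kind": "trajectory",
        "seed": int(seed),
        "n_frames": int(n_frames),
        "epitopes": [
            {
                "residues": [[c, int(r)] for c, r in sets[e]],
                "fraction": fractions[e],
                "n_bound_frames": counts[e],
                "occupancy_pct": 100.0 * counts[e] / n_frames,
                "frames": sorted(int(i) for i in np.flatnonzero(assignment == e)),
            }
            for e in range(len(sets))
        ],
    }
    if out_pdb is not None:
        out_pdb = Path(out_pdb)
        _write_multimodel_pdb(traj, mock_protein, out_pdb, ligand_resname)
        write_manifest(manifest, out_pdb.with_suffix(".manifest.json"))
    return traj, manifest


def _write_multimodel_pdb(traj: Trajectory, bundle: MockBundle, path: Path,
                          ligand_resname: str) -> None:
    """Write protein + ligand frames as a multi-model PDB via MDAnalysis."""
    import warnings

    import MDAnalysis as mda

    n_prot = bundle.coords.shape[0]
    n_lig = traj.ligand_coords.shape[1]
    n_atoms = n_prot + n_lig
    res_keys = list(dict.fromkeys(bundle.atom_residues))
    res_of_atom = {key: idx for idx, key in enumerate(res_keys)}
    atom_resindex = [res_of_atom[k] for k in bundle.atom_residues] + \
                    [len(res_keys)] * n_lig
    n_res = len(res_keys) + 1
    chains = sorted({c for c, _ in res_keys})
    seg_of_chain = {c: i for i, c in enumerate(chains)}
    residue_segindex = [seg_of_chain[c] for c, _ in res_keys] + [len(chains)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n_atoms, n_residues=n_res,
                               n_segments=len(chains) + 1,
                               atom_resindex=atom_resindex,
                               residue_segindex=residue_segindex,
                               trajectory=True)
        u.add_TopologyAttr("names", bundle.atom_names +
                           [f"C{k + 1}" for k in range(n_lig)])
        u.add_TopologyAttr("resnames", ["ALA"] * len(res_keys) + [ligand_resname])
        u.add_TopologyAttr("resids", [r for _, r in res_keys] + [1])
        u.add_TopologyAttr("segids", chains + ["L"])
        u.add_TopologyAttr("chainIDs", [c for c, _ in bundle.atom_residues] +
                           ["L"] * n_lig)
        u.add_TopologyAttr("elements", ["C"] * n_atoms)
        u.add_TopologyAttr("occupancies", [1.0] * n_atoms)
        u.add_TopologyAttr("tempfactors", [0.0] * n_atoms)
        frames = np.concatenate([traj.protein_coords, traj.ligand_coords], axis=1)
        u.load_new(frames.astype(np.float32), order="fac")
        with mda.Writer(str(path), n_atoms, multiframe=True) as writer:
            for _ in u.trajectory:
                writer.write(u.atoms)


# ---------------------------------------------------------------------------
# PMF profiles and calibration sets
# ---------------------------------------------------------------------------

def gen_pmf_profile(barrier_height: float = 5.0, well_depth: float = 1.5,
                    barrier_width: float = 4.0, well_width: float = 3.0,
                    well_center: float = 12.0,
                    z_range: tuple[float, float] = (-40.0, 40.0),
                    step: float = 0.1, seed: int = 0,
                    out: str | Path | None = None) -> tuple[pd.DataFrame, dict]:
    """Parametric PMF: central Gaussian barrier + symmetric interface wells.

    The profile is pinned to 0 in the water phase by construction (all
    Gaussian components decay well before the ends of the z range).
    """
    z = np.arange(z_range[0], z_range[1] + 0.5 * step, step)
    dG = barrier_height * np.exp(-z ** 2 / (2.0 * barrier_width ** 2))
    for c in (well_center, -well_center):
        dG = dG - well_depth * np.exp(-(z - c) ** 2 / (2.0 * well_width ** 2))
    df = pd.DataFrame({"z_angstrom": z, "dG_kcal_mol": dG})
    manifest = {"kind": "pmf_profile", "seed": int(seed),
                "barrier_height_kcal": float(barrier_height),
                "well_depth_kcal": float(well_depth),
                "barrier_width_A": float(barrier_width),
                "well_width_A": float(well_width)}
    _maybe_write_csv(df, out, manifest)
    return df, manifest


def gen_calibration_set(true_slope: float = 0.27, true_intercept: float = -5.3,
                        n: int = 9, x_range: tuple[float, float] = (-5.0, 1.0),
                        scatter_sd: float = 0.08, seed: int = 0,
                        out: str | Path | None = None) -> tuple[pd.DataFrame, dict]:
    """Reference calibration pairs on a planted line plus Gaussian scatter.

    Defaults to nine reference compounds, mirroring the PAMPA calibration
    design of the supported study.
    """
    if n < 2:
        raise ValueError("need at least 2 calibration compounds")
    rng = np.random.default_rng(seed)
    x = np.linspace(*x_range, n)
    y = true_intercept + true_slope * x + rng.normal(0.0, scatter_sd, size=n)
    df = pd.DataFrame({"log_peff_pmf": x, "log_peff_pampa": y})
    manifest = {"kind": "calibration_set", "seed": int(seed),
                "true_slope": float(true_slope),
                "true_intercept": float(true_intercept),
                "scatter_sd": float(scatter_sd), "n": int(n)}
    _maybe_write_csv(df, out, manifest)
    return df, manifest
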