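"""Molecule data model, structure I/O, and pharmacophore feature typing.

This module provides the substrate of the ligand-based screening stage: a
lightweight :class:`Molecule` container (explicit atoms with 3D coordinates,
bonds, formal charges), readers/writers for the standard small-molecule text
formats (SDF / MOL V2000, XYZ), a data-driven pharmacophore feature typer
covering the six standard color-feature kinds (donor, acceptor, anion,
cation, hydrophobe, ring), and a molecular-weight filter.

Feature typing is rule based.  The shipped default ruleset
(``data/color_features.yaml``) uses SMARTS patterns for the polar/ionic
kinds, smallest-set-of-smallest-rings centroids for ring features, and
connected carbon clusters for hydrophobes.  The ruleset is data, not code:
users may supply their own YAML file with the same schema.  Exact parity
with proprietary color-feature assigners is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import rdmolops

__all__ = [
    "Molecule",
    "PharmacophoreFeature",
    "FEATURE_KINDS",
    "StructureParseError",
    "FeatureTypingError",
    "read_structures",
    "write_sdf",
    "load_feature_rules",
    "assign_features",
    "mw_filter",
]

FEATURE_KINDS = ("donor", "acceptor", "anion", "cation", "hydrophobe", "ring")

_PT = Chem.GetPeriodicTable()


class StructureParseError(ValueError):
    """A structure file or record could not be parsed."""


class FeatureTypingError(ValueError):
    """A molecule is not suitable for pharmacophore feature assignment."""


@dataclass
class Molecule:
    """A small molecule with explicit 3D coordinates.

    Parameters
    ----------
    name:
        Identifier (record name from the source file, or synthetic id).
    elements:
        Element symbol per atom (normalized capitalization, e.g. ``"Cl"``).
    coords:
        ``(n_atoms, 3)`` Cartesian coordinates in Angstrom.
    formal_charges:
        Integer formal charge per atom.
    bonds:
        ``(i, j, order)`` triples with 0-based atom indices; empty for
        formats that carry no connectivity (XYZ).
    """

    name: str
    elements: list[str]
    coords: np.ndarray
    formal_charges: list[int] = field(default_factory=list)
    bonds: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) < 1:
            raise ValueError("a Molecule needs at least one atom")
        if self.coords.shape[0] != len(self.elements):
            raise ValueError("coords/elements length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if not self.formal_charges:
            self.formal_charges = [0] * len(self.elements)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def molecular_weight(self) -> float:
        """Sum of average atomic masses in Da."""
        return float(sum(_PT.GetAtomicWeight(e) for e in self.elements))

    def heavy_coords(self) -> np.ndarray:
        """Coordinates of all non-hydrogen atoms."""
        mask = [e != "H" for e in self.elements]
        return self.coords[np.asarray(mask, dtype=bool)]

    # -- RDKit bridge ------------------------------------------------------

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        """Build an RDKit molecule (with conformer) from this record."""
        rw = Chem.RWMol()
        for el, q in zip(self.elements, self.formal_charges):
            a = Chem.Atom(el)
            a.SetFormalCharge(int(q))
            a.SetNoImplicit(False)
            rw.AddAtom(a)
        order_map = {
            1: Chem.BondType.SINGLE,
            2: Chem.BondType.DOUBLE,
            3: Chem.BondType.TRIPLE,
            4: Chem.BondType.AROMATIC,
        }
        for i, j, o in self.bonds:
            rw.AddBond(int(i), int(j), order_map.get(int(o), Chem.BondType.SINGLE))
        conf = Chem.Conformer(self.n_atoms)
        for i, xyz in enumerate(self.coords):
            conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
        mol = rw.GetMol()
        mol.AddConformer(conf)
        mol.SetProp("_Name", self.name)
        if sanitize:
            Chem.SanitizeMol(mol)
        return mol

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, name: str | None = None) -> "Molecule":
        if mol.GetNumConformers() == 0:
            raise StructureParseError("RDKit molecule has no 3D conformer")
        conf = mol.GetConformer()
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        coords = np.array(
            [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())],
            dtype=float,
        )
        charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
        rev = {
            Chem.BondType.SINGLE: 1,
            Chem.BondType.DOUBLE: 2,
            Chem.BondType.TRIPLE: 3,
            Chem.BondType.AROMATIC: 4,
        }
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), rev.get(b.GetBondType(), 1))
            for b in mol.GetBonds()
        ]
        if name is None:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else "mol"
        return cls(name=name, elements=elements, coords=coords,
                   formal_charges=charges, bonds=bonds)


@dataclass(frozen=True)
class PharmacophoreFeature:
    """A typed pharmacophore point: kind, 3D centroid (A), Gaussian radius (A)."""

    kind: str
    centroid: tuple[float, float, float]
    radius: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("feature radius must be positive")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=float)


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

def _read_xyz(path: Path) -> list[Molecule]:
    """Read a (possibly multi-record) XYZ file.

    XYZ carries no connectivity, so the returned Molecules have empty bond
    lists; downstream feature typing will reject them with guidance.
    """
    lines = path.read_text().splitlines()
    mols: list[Molecule] = []
    pos = 0
    record = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        record += 1
        try:
            n = int(lines[pos].split()[0])
            comment = lines[pos + 1].strip() if pos + 1 < len(lines) else ""
            body = lines[pos + 2 : pos + 2 + n]
            if len(body) < n:
                raise ValueError("truncated record")
            elements, coords = [], []
            for ln in body:
                parts = ln.split()
                elements.append(parts[0].capitalize())
                coords.append([float(v) for v in parts[1:4]])
        except (ValueError, IndexError) as exc:
            raise StructureParseError(
                f"XYZ record {record} in {path.name} is unparseable: {exc}"
            ) from exc
        mols.append(Molecule(name=comment or f"xyz_{record}", elements=elements,
                             coords=np.array(coords), bonds=[]))
        pos += 2 + n
    if not mols:
        raise StructureParseError(f"{path.name}: no XYZ records found")
    return mols


def read_structures(path: str | Path, fmt: str | None = None) -> list[Molecule]:
    """Read molecules from an SDF, MOL (V2000) or XYZ file.

    Coordinates are preserved exactly as written; element symbols are
    normalized.  An unparseable record raises :class:`StructureParseError`
    naming the (1-based) record index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "mol":
        mol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=True)
        if mol is None:
            raise StructureParseError(f"record 1 of {path.name} is unparseable")
        return [Molecule.from_rdkit(mol, name=path.stem)]
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        mols = []
        for i, mol in enumerate(supplier, start=1):
            if mol is None:
                raise StructureParseError(f"record {i} of {path.name} is unparseable")
            mols.append(Molecule.from_rdkit(mol, name=None))
        if not mols:
            raise StructureParseError(f"{path.name}: no SDF records found")
        return mols
    raise ValueError(f"unsupported format {fmt!r} (expected SDF, MOL or XYZ)")


def write_sdf(mols: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules to an SDF (V2000) file, preserving coordinates."""
    writer = Chem.SDWriter(str(path))
    try:
        for m in mols:
            writer.write(m.to_rdkit())
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# pharmacophore feature typing
# ---------------------------------------------------------------------------

def load_feature_rules(path: str | Path | None = None) -> dict:
    """Load a feature-typing ruleset (YAML). None loads the shipped default.

    Schema::

        radius: 1.0                  # Gaussian radius of all features, A
        donor:    {smarts: [...]}    # placed at each matched heteroatom
        acceptor: {smarts: [...]}
        anion:    {smarts: [...]}    # placed at group centroid
        cation:   {smarts: [...]}
        hydrophobe: {min_cluster_size: 2}
        ring: {}                     # SSSR centroids, always on
    """
    if path is None:
        text = resources.files("leadscope.data").joinpath(
            "color_features.yaml").read_text()
    else:
        text = Path(path).read_text()
    rules = yaml.safe_load(text)
    if not isinstance(rules, dict):
        raise ValueError("feature ruleset must be a mapping")
    return rules


def _match_atoms(mol: Chem.Mol, smarts_list: Sequence[str]) -> list[tuple[int, ...]]:
    matches: list[tuple[int, ...]] = []
    for smarts in smarts_list:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS in ruleset: {smarts!r}")
        matches.extend(mol.GetSubstructMatches(patt))
    return matches


def assign_features(mol: Molecule, rules: dict | None = None) -> list[PharmacophoreFeature]:
    """Assign pharmacophore color features to a molecule.

    Requires connectivity (bonds) and explicit hydrogens: implicit-hydrogen
    inputs are rejected because donor counts would silently be wrong.
    The result is deterministic (sorted by kind, then coordinates) and
    permutation invariant in the atom order.
    """
    if not mol.bonds:
        raise FeatureTypingError(
            "molecule has no bonds; feature perception needs connectivity "
            "(supply SDF/MOL input rather than XYZ)"
        )
    rules = rules if rules is not None else load_feature_rules()
    rd = mol.to_rdkit()
    for atom in rd.GetAtoms():
        if atom.GetNumImplicitHs() > 0:
            raise FeatureTypingError(
                "molecule carries implicit hydrogens; supply explicit-H "
                "structures so donor features are counted correctly"
            )
    radius = float(rules.get("radius", 1.0))
    coords = mol.coords
    feats: list[PharmacophoreFeature] = []

    def add(kind: str, xyz: np.ndarray) -> None:
        feats.append(PharmacophoreFeature(kind, tuple(float(v) for v in xyz), radius))

    # ionic groups first: their atoms are excluded from donor/acceptor typing
    claimed: set[int] = set()
    for kind in ("anion", "cation"):
        block = rules.get(kind) or {}
        seen_groups: set[frozenset[int]] = set()
        for match in _match_atoms(rd, block.get("smarts", [])):
            group = frozenset(match)
            if group & claimed or group in seen_groups:
                continue
            seen_groups.add(group)
            claimed |= group
            add(kind, coords[list(match)].mean(axis=0))

    for kind in ("donor", "acceptor"):
        block = rules.get(kind) or {}
        seen_atoms: set[int] = set()
        for match in _match_atoms(rd, block.get("smarts", [])):
            idx = match[0]  # the heteroatom anchors the feature
            if idx in claimed or idx in seen_atoms:
                continue
            seen_atoms.add(idx)
            add(kind, coords[idx])

    # ring features: one per SSSR ring, at the ring-atom centroid
    for ring in rdmolops.GetSSSR(rd):
        idx = list(ring)
        add("ring", coords[idx].mean(axis=0))

    # hydrophobes: connected clusters of carbons with no heteroatom neighbor
    hblock = rules.get("hydrophobe") or {}
    min_size = int(hblock.get("min_cluster_size", 2))
    eligible = set()
    for atom in rd.GetAtoms():
        if atom.GetSymbol() != "C":
            continue
        if any(n.GetSymbol() not in ("C", "H") for n in atom.GetNeighbors()):
            continue
        eligible.add(atom.GetIdx())
    seen: set[int] = set()
    for idx in sorted(eligible):
        if idx in seen:
            continue
        cluster = {idx}
        stack = [idx]
        while stack:
            cur = stack.pop()
            for n in rd.GetAtomWithIdx(cur).GetNeighbors():
                j = n.GetIdx()
                if j in eligible and j not in cluster:
                    cluster.add(j)
                    stack.append(j)
        seen |= cluster
        if len(cluster) >= min_size:
            add("hydrophobe", coords[sorted(cluster)].mean(axis=0))

    feats.sort(key=lambda f: (f.kind, tuple(round(v, 6) for v in f.centroid)))
    return feats


def mw_filter(mols: Sequence[Molecule], max_mw: float) -> list[Molecule]:
    """Keep molecules with molecular weight strictly below ``max_mw`` Da."""
    if max_mw <= 0:
        raise ValueError("max_mw must be positive")
    return [m for m in mols if m.molecular_weight < max_mw]
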