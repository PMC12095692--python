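import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from leadscope.chemlib import Molecule
from leadscope.synthetic_data import example_template


def molecule_from_smiles(smiles: str, name: str, seed: int = 7) -> Molecule:
    """Explicit-H 3D molecule from SMILES (deterministic embedding)."""
    mol = Chem.MolFromSmiles(smiles)
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    mol.SetProp("_Name", name)
    return Molecule.from_rdkit(mol)


@pytest.fixture(scope="session")
def template():
    return example_template()


@pytest.fixture(scope="session")
def benzene():
    return molecule_from_smiles("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def methane():
    return molecule_from_smiles("C", "methane")


@pytest.fixture(scope="session")
def acetate():
    return molecule_from_smiles("CC([O-])=O", "acetate")


def random_rigid_motion(seed: int) -> tuple[np.ndarray, np.ndarray]:
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-6.0, 6.0, size=3)
    return R, t
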