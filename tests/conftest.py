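import numpy as np
import pytest

from usrcatkit import ConformerRecord, FixtureSpec, generate_cloud


def _record_from_smiles(smiles: str, name: str, seed: int = 1) -> ConformerRecord:
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    conf = mol.GetConformer()
    coords = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
    )
    return ConformerRecord(
        mol_id=name,
        conf_id=0,
        coords=coords,
        elements=[a.GetSymbol() for a in mol.GetAtoms()],
        is_hydrogen=np.array([a.GetAtomicNum() == 1 for a in mol.GetAtoms()]),
        mol=mol,
    )


@pytest.fixture(scope="session")
def ethanol():
    return _record_from_smiles("CCO", "ethanol")


@pytest.fixture(scope="session")
def benzene():
    return _record_from_smiles("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def butane():
    return _record_from_smiles("CCCC", "butane")


@pytest.fixture
def cloud_factory():
    """Labeled point clouds keyed by seed: (record, subsets)."""

    def make(seed: int, n_atoms=(3, 40), **kwargs):
        spec = FixtureSpec(seed=seed, n_atoms=n_atoms, **kwargs)
        return generate_cloud(spec, f"cloud_{seed}")

    return make


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
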