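import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_flexible_smiles():
    """Small (<=7 heavy atoms) fixture molecules; cheap to embed."""
    from rdkit import Chem

    from confdesc.fixtures import fixture_smiles

    return [
        s for s in fixture_smiles()
        if Chem.MolFromSmiles(s).GetNumHeavyAtoms() <= 7
    ][:60]


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.normal(scale=5.0, size=3)
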