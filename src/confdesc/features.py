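"""One-hot atom and bond featurization shared by the 2D and 3D models.

Atoms carry one-hot blocks for element type, valence (outer-shell) electrons,
chirality tag, formal charge, aromaticity, ring membership and smallest ring
size, heavy-atom degree and total attached hydrogens; every block has an
"other" slot and sums to exactly one.  Bonds carry bond type, conjugation,
ring membership and stereochemistry blocks.  The 2D models use heavy-atom
graphs (hydrogens appear only through the attached-H block); the 3D models
reuse the identical atom featurizer on the explicit-hydrogen molecule and do
not featurize bonds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

ATOM_TYPES = ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I", "Sn", "Se"]
VALENCE_ELECTRONS = [1, 2, 3, 4, 5, 6, 7, 8]
CHIRAL_TAGS = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
]
FORMAL_CHARGES = [-2, -1, 0, 1, 2]
RING_SIZES = [0, 3, 4, 5, 6, 7, 8]  # 0 = not in a ring
DEGREES = [0, 1, 2, 3, 4, 5]
TOTAL_HS = [0, 1, 2, 3, 4]

BOND_TYPES = [
    Chem.BondType.SINGLE, Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE, Chem.BondType.AROMATIC,
]
BOND_STEREO = [
    Chem.BondStereo.STEREONONE, Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS, Chem.BondStereo.STEREOTRANS,
]


def _one_hot(value, choices: list) -> list[float]:
    """One-hot with a trailing 'other' slot; always sums to 1."""
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


ATOM_FEATURE_DIM = (len(ATOM_TYPES) + 1) + (len(VALENCE_ELECTRONS) + 1) \
    + (len(CHIRAL_TAGS) + 1) + (len(FORMAL_CHARGES) + 1) + 2 \
    + (len(RING_SIZES) + 1) + (len(DEGREES) + 1) + (len(TOTAL_HS) + 1)
BOND_FEATURE_DIM = (len(BOND_TYPES) + 1) + 2 + 2 + (len(BOND_STEREO) + 1)

_PT = Chem.GetPeriodicTable()


def atom_features(atom: Chem.Atom) -> list[float]:
    mol = atom.GetOwningMol()
    ring_info = mol.GetRingInfo()
    idx = atom.GetIdx()
    if atom.IsInRing():
        ring_size = min(len(r) for r in ring_info.AtomRings() if idx in r)
    else:
        ring_size = 0
    feats = []
    feats += _one_hot(atom.GetSymbol(), ATOM_TYPES)
    feats += _one_hot(_PT.GetNOuterElecs(atom.GetAtomicNum()), VALENCE_ELECTRONS)
    feats += _one_hot(atom.GetChiralTag(), CHIRAL_TAGS)
    feats += _one_hot(atom.GetFormalCharge(), FORMAL_CHARGES)
    feats += [1.0, 0.0] if not atom.GetIsAromatic() else [0.0, 1.0]
    feats += _one_hot(ring_size, RING_SIZES)
    feats += _one_hot(atom.GetDegree(), DEGREES)
    feats += _one_hot(atom.GetTotalNumHs(includeNeighbors=True), TOTAL_HS)
    return feats


def bond_features(bond: Chem.Bond) -> list[float]:
    feats = []
    feats += _one_hot(bond.GetBondType(), BOND_TYPES)
    feats += [1.0, 0.0] if not bond.GetIsConjugated() else [0.0, 1.0]
    feats += [1.0, 0.0] if not bond.IsInRing() else [0.0, 1.0]
    feats += _one_hot(bond.GetStereo(), BOND_STEREO)
    return feats


@dataclass
class Graph2D:
    """Heavy-atom molecular graph with one-hot node/edge features."""

    x: np.ndarray          # (n_atoms, ATOM_FEATURE_DIM)
    edge_index: np.ndarray  # (2, 2*n_bonds) directed, both directions
    edge_attr: np.ndarray  # (2*n_bonds, BOND_FEATURE_DIM)

    @property
    def n_atoms(self) -> int:
        return self.x.shape[0]


class FeaturizationError(ValueError):
    pass


def featurize_2d(mol_or_smiles) -> Graph2D:
    """Heavy-atom graph with the documented one-hot block layout.

    Accepts a SMILES string or an RDKit molecule (explicit hydrogens are
    folded into the attached-H feature).
    """
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise FeaturizationError(f"SMILES failed to parse: {mol_or_smiles!r}")
    else:
        mol = mol_or_smiles
        if mol is None:
            raise FeaturizationError("molecule is None")
        if any(a.GetAtomicNum() == 1 for a in mol.GetAtoms()):
            mol = Chem.RemoveHs(mol)

    x = np.array([atom_features(a) for a in mol.GetAtoms()], dtype=float)
    src, dst, eattr = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = bond_features(bond)
        src += [i, j]
        dst += [j, i]
        eattr += [f, f]
    edge_index = (np.array([src, dst], dtype=np.intp)
                  if src else np.zeros((2, 0), dtype=np.intp))
    edge_attr = (np.array(eattr, dtype=float)
                 if eattr else np.zeros((0, BOND_FEATURE_DIM)))
    return Graph2D(x=x, edge_index=edge_index, edge_attr=edge_attr)


def atom_features_with_h(mol: Chem.Mol) -> np.ndarray:
    """Atom feature matrix for the explicit-hydrogen molecule (3D models)."""
    if not any(a.GetAtomicNum() == 1 for a in mol.GetAtoms()):
        mol = Chem.AddHs(mol)
    return np.array([atom_features(a) for a in mol.GetAtoms()], dtype=float)
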