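"""Conformer ensembles: generation, deduplication, energy windowing, capping.

Ensembles are generated with RDKit's ETKDG distance-geometry embedding and
relaxed with the MMFF94 force field; the resulting force-field energies,
re-zeroed to the ensemble minimum, are the relative energies used for
Boltzmann weighting downstream.  Externally computed ensembles (e.g. from a
quantum-chemistry workflow) are ingested with whatever energies accompany
them; the ``source`` label records the provenance.

All coordinates are Cartesian angstrom; energies are kcal/mol relative to the
ensemble minimum.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from rdkit import Chem
from rdkit.Chem import AllChem

from .moiety import mol_with_hs


class EmbedError(RuntimeError):
    """3D embedding or force-field setup failed for a molecule."""


@dataclass
class Conformer:
    coords: np.ndarray  # (n_atoms, 3) angstrom
    rel_energy: float  # kcal/mol >= 0
    source: str = "generated"  # generated | ingested

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")


@dataclass
class ConformerEnsemble:
    """Ordered (ascending energy) conformers sharing one atom ordering."""

    molecule_id: str
    conformers: list[Conformer]
    element_symbols: list[str]
    mol: Chem.Mol | None = None  # connectivity (explicit H), no conformers required
    smiles: str | None = None

    def __post_init__(self) -> None:
        n = len(self.element_symbols)
        for c in self.conformers:
            if c.coords.shape[0] != n:
                raise ValueError("conformer atom count does not match element_symbols")

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def rel_energies(self) -> np.ndarray:
        return np.array([c.rel_energy for c in self.conformers])

    def finalized(self) -> "ConformerEnsemble":
        """Re-zero energies to the minimum and stable-sort ascending."""
        if not self.conformers:
            return self
        e = self.rel_energies
        e0 = e.min()
        confs = [replace(c, rel_energy=c.rel_energy - e0) for c in self.conformers]
        order = np.argsort([c.rel_energy for c in confs], kind="stable")
        return replace(self, conformers=[confs[i] for i in order])


def generate_ensemble(
    smiles: str,
    n_embed: int = 50,
    seed: int = 42,
    molecule_id: str | None = None,
) -> ConformerEnsemble:
    """ETKDG-embed up to ``n_embed`` conformers and relax them with MMFF94.

    Deterministic for a fixed ``seed``.  Raises :class:`EmbedError` when the
    molecule cannot be embedded or the force field cannot be set up.
    """
    mol = mol_with_hs(smiles)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.useRandomCoords = False
    cids = AllChem.EmbedMultipleConfs(mol, numConfs=int(n_embed), params=params)
    if len(cids) == 0:
        raise EmbedError(f"ETKDG embedding failed for {molecule_id or smiles!r}")

    if AllChem.MMFFHasAllMoleculeParams(mol):
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=1000)
    else:  # rare elements outside MMFF94 coverage: relax with UFF instead
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=1000)
    energies = [e for _converged, e in results]
    if any(e is None or not np.isfinite(e) for e in energies):
        raise EmbedError(f"force-field optimization failed for {molecule_id or smiles!r}")

    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    conformers = [
        Conformer(coords=np.array(mol.GetConformer(cid).GetPositions()),
                  rel_energy=float(e), source="generated")
        for cid, e in zip(cids, energies)
    ]
    ens = ConformerEnsemble(
        molecule_id=molecule_id or smiles,
        conformers=conformers,
        element_symbols=symbols,
        mol=Chem.Mol(mol),
        smiles=smiles,
    )
    return ens.finalized()


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Best-fit RMSD between two (n, 3) coordinate sets after centering."""
    a = np.asarray(a, float) - np.mean(a, axis=0)
    b = np.asarray(b, float) - np.mean(b, axis=0)
    if len(a) == 1:  # single point: identical after centering
        return 0.0
    with warnings.catch_warnings():
        # degenerate (collinear/planar) sets only make the rotation non-unique;
        # the residual, which is all we use, is still well defined
        warnings.simplefilter("ignore", UserWarning)
        _rot, rssd = Rotation.align_vectors(a, b)
    return float(rssd) / np.sqrt(len(a))


def dedup(ensemble: ConformerEnsemble, rmsd_cut: float = 0.5) -> ConformerEnsemble:
    """Greedy energy-ordered pruning of near-duplicate conformers.

    A conformer is dropped when its best-fit heavy-atom RMSD to any already
    kept (lower-energy) conformer is below ``rmsd_cut`` angstrom, so the kept
    set always retains the lower-energy representative of each cluster.
    """
    if not ensemble.conformers:
        raise ValueError("cannot dedup an empty ensemble")
    ens = ensemble.finalized()
    heavy = [i for i, s in enumerate(ens.element_symbols) if s != "H"]
    if not heavy:  # e.g. bare H2: fall back to all atoms
        heavy = list(range(len(ens.element_symbols)))
    kept: list[Conformer] = []
    for conf in ens.conformers:
        ha = conf.coords[heavy]
        if all(kabsch_rmsd(ha, k.coords[heavy]) >= rmsd_cut for k in kept):
            kept.append(conf)
    return replace(ens, conformers=kept)


def energy_window(ensemble: ConformerEnsemble, window: float = 5.0) -> ConformerEnsemble:
    """Keep conformers with relative energy <= ``window`` kcal/mol (inclusive)."""
    if window < 0:
        raise ValueError("window must be >= 0")
    ens = ensemble.finalized()
    kept = [c for c in ens.conformers if c.rel_energy <= window]
    return replace(ens, conformers=kept)


def cap_for_model(ensemble: ConformerEnsemble, k: int = 20) -> ConformerEnsemble:
    """Keep the ``k`` lowest-energy conformers (stable order, ties keep the
    earlier conformer)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ens = ensemble.finalized()
    return replace(ens, conformers=ens.conformers[:k])


# ---------------------------------------------------------------------------
# External formats: multi-frame XYZ and SDF V2000 with an energy tag
# ---------------------------------------------------------------------------

_XYZ_COMMENT = re.compile(r"^(?P<id>\S+)\s+rel_energy=(?P<e>[-+0-9.eE]+)\s*$")


def write_xyz(ensemble: ConformerEnsemble, path: str) -> None:
    """Multi-frame XYZ; the comment line holds '<molecule_id> rel_energy=<kcal/mol>'."""
    with open(path, "w") as fh:
        for conf in ensemble.conformers:
            fh.write(f"{len(ensemble.element_symbols)}\n")
            fh.write(f"{ensemble.molecule_id} rel_energy={conf.rel_energy:.10g}\n")
            for sym, (x, y, z) in zip(ensemble.element_symbols, conf.coords):
                fh.write(f"{sym} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path: str) -> list[ConformerEnsemble]:
    """Read one or more ensembles from a multi-frame XYZ file."""
    frames: dict[str, tuple[list[str], list[Conformer]]] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        m = _XYZ_COMMENT.match(lines[i + 1].strip())
        if m is None:
            raise ValueError(f"bad XYZ comment line: {lines[i + 1]!r}")
        mol_id, e = m.group("id"), float(m.group("e"))
        symbols, coords = [], []
        for row in lines[i + 2 : i + 2 + n]:
            parts = row.split()
            symbols.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        entry = frames.setdefault(mol_id, (symbols, []))
        if entry[0] != symbols:
            raise ValueError(f"inconsistent atom ordering for {mol_id!r}")
        entry[1].append(Conformer(np.array(coords), e, source="ingested"))
        i += 2 + n
    return [
        ConformerEnsemble(mol_id, confs, syms).finalized()
        for mol_id, (syms, confs) in frames.items()
    ]


ENERGY_TAG = "REL_ENERGY_KCAL"


def write_sdf(ensembles: list[ConformerEnsemble], path: str) -> None:
    """SDF V2000, one record per conformer, energy in the <REL_ENERGY_KCAL> tag."""
    writer = Chem.SDWriter(path)
    writer.SetForceV3000(False)
    try:
        for ens in ensembles:
            if ens.mol is None:
                raise ValueError(
                    f"ensemble {ens.molecule_id!r} has no connectivity; use write_xyz"
                )
            for conf in ens.conformers:
                m = Chem.Mol(ens.mol)
                m.RemoveAllConformers()
                c = Chem.Conformer(m.GetNumAtoms())
                for i, xyz in enumerate(conf.coords):
                    c.SetAtomPosition(i, [float(v) for v in xyz])
                m.AddConformer(c, assignId=True)
                m.SetProp("_Name", ens.molecule_id)
                m.SetProp(ENERGY_TAG, f"{conf.rel_energy:.10g}")
                writer.write(m)
    finally:
        writer.close()


def read_sdf(path: str) -> list[ConformerEnsemble]:
    """Read ensembles back from an SDF written by :func:`write_sdf`."""
    grouped: dict[str, tuple[Chem.Mol, list[str], list[Conformer]]] = {}
    for mol in Chem.SDMolSupplier(path, removeHs=False, sanitize=True):
        if mol is None:
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else "mol"
        e = float(mol.GetProp(ENERGY_TAG)) if mol.HasProp(ENERGY_TAG) else 0.0
        coords = np.array(mol.GetConformer().GetPositions())
        syms = [a.GetSymbol() for a in mol.GetAtoms()]
        entry = grouped.setdefault(mol_id, (mol, syms, []))
        if entry[1] != syms:
            raise ValueError(f"inconsistent atom ordering for {mol_id!r}")
        entry[2].append(Conformer(coords, e, source="ingested"))
    return [
        ConformerEnsemble(mol_id, confs, syms, mol=mol).finalized()
        for mol_id, (mol, syms, confs) in grouped.items()
    ]
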