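"""Conformer generation, deduplication, windowing, capping and file formats."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from confdesc.ensembles import (
    Conformer,
    ConformerEnsemble,
    cap_for_model,
    dedup,
    energy_window,
    generate_ensemble,
    kabsch_rmsd,
    read_sdf,
    read_xyz,
    write_sdf,
    write_xyz,
)


def _toy_ensemble(energies, n_atoms=3, seed=0):
    rng = np.random.default_rng(seed)
    confs = [Conformer(rng.normal(size=(n_atoms, 3)), float(e)) for e in energies]
    return ConformerEnsemble("toy", confs, ["C"] * n_atoms).finalized()


class TestGenerate:
    def test_methane_is_rigid(self):
        ens = dedup(generate_ensemble("C", n_embed=5, seed=1))
        assert len(ens) == 1

    def test_butane_has_anti_and_gauche(self):
        """The C-C-C-C torsion minima: anti at 0, gauche above it.

        Oracle: an MMFF94 torsion scan of butane locates the anti minimum as
        global; a distinct kept conformer must exist ~0.5-1 kcal/mol up.
        """
        ens = dedup(generate_ensemble("CCCC", n_embed=50, seed=1), 0.5)
        assert len(ens) >= 2
        assert ens.conformers[0].rel_energy == 0.0
        # torsion-scan oracle for the gauche-anti gap
        mol = Chem.AddHs(Chem.MolFromSmiles("CCCC"))
        AllChem.EmbedMolecule(mol, randomSeed=7)
        heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 6]
        energies = []
        for deg in range(0, 360, 10):
            m = Chem.Mol(mol)
            Chem.rdMolTransforms.SetDihedralDeg(m.GetConformer(), *heavy, float(deg))
            ff = AllChem.MMFFGetMoleculeForceField(
                m, AllChem.MMFFGetMoleculeProperties(m))
            for idx in heavy:
                ff.MMFFAddPositionConstraint(idx, 0.0, 1e4)
            ff.Minimize()
            energies.append(ff.CalcEnergy())
        energies = np.array(energies)
        # scan shows two wells: global near 180 (anti), local near +-60 (gauche)
        anti = energies[18]
        gauche = min(energies[6], energies[30])
        assert gauche - anti > 0.3
        gap = ens.conformers[1].rel_energy
        assert 0.2 < gap < 2.0

    def test_same_seed_reproduces_coordinates(self):
        a = generate_ensemble("CCCC", n_embed=10, seed=3)
        b = generate_ensemble("CCCC", n_embed=10, seed=3)
        for ca, cb in zip(a.conformers, b.conformers):
            np.testing.assert_array_equal(ca.coords, cb.coords)
            assert ca.rel_energy == cb.rel_energy

    def test_unembeddable_raises(self):
        with pytest.raises(Exception):
            generate_ensemble("not a smiles")


class TestDedup:
    def test_identical_geometries_collapse(self):
        c = np.random.default_rng(0).normal(size=(4, 3))
        ens = ConformerEnsemble(
            "m", [Conformer(c, 0.0), Conformer(c.copy(), 0.3)], ["C"] * 4
        )
        assert len(dedup(ens, 0.5)) == 1

    def test_kept_representative_is_lower_energy(self):
        c = np.random.default_rng(0).normal(size=(4, 3))
        ens = ConformerEnsemble(
            "m", [Conformer(c, 0.5), Conformer(c.copy(), 0.0)], ["C"] * 4
        )
        out = dedup(ens, 0.5)
        assert len(out) == 1 and out.conformers[0].rel_energy == 0.0

    def test_anti_gauche_butane_both_kept(self):
        """Kabsch-aligned heavy-atom RMSD between anti and gauche > 0.5 A."""
        ens = dedup(generate_ensemble("CCCC", n_embed=30, seed=1), 0.5)
        heavy = [i for i, s in enumerate(ens.element_symbols) if s != "H"]
        r = kabsch_rmsd(ens.conformers[0].coords[heavy],
                        ens.conformers[1].coords[heavy])
        assert r > 0.5

    def test_idempotent(self):
        ens = generate_ensemble("CCCCC", n_embed=20, seed=2)
        once = dedup(ens, 0.5)
        twice = dedup(once, 0.5)
        assert len(once) == len(twice)
        for a, b in zip(once.conformers, twice.conformers):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_singleton_unchanged(self):
        ens = _toy_ensemble([0.0])
        assert len(dedup(ens, 0.5)) == 1


class TestWindowAndCap:
    def test_window_boundary_is_inclusive(self):
        ens = _toy_ensemble([0.0, 3.2, 5.0, 5.01])
        assert list(energy_window(ens, 5.0).rel_energies) == [0.0, 3.2, 5.0]

    def test_window_zero_keeps_only_minimum(self):
        ens = _toy_ensemble([0.0, 0.5, 1.0])
        assert len(energy_window(ens, 0.0)) == 1

    def test_window_wider_than_range_is_identity(self):
        ens = _toy_ensemble([0.0, 1.0, 2.0])
        assert len(energy_window(ens, 10.0)) == 3

    def test_cap_keeps_k_lowest(self):
        ens = _toy_ensemble(np.linspace(0, 8, 35))
        out = cap_for_model(ens, 20)
        assert len(out) == 20
        assert out.rel_energies.max() < 5.0

    def test_cap_larger_than_ensemble_is_identity(self):
        ens = _toy_ensemble([0.0, 1.0, 2.0])
        assert len(cap_for_model(ens, 20)) == 3

    def test_cap_tie_break_keeps_earlier_conformer(self):
        rng = np.random.default_rng(1)
        confs = [Conformer(rng.normal(size=(3, 3)), e) for e in [0.0, 1.0, 1.0]]
        ens = ConformerEnsemble("m", confs, ["C"] * 3)
        out = cap_for_model(ens, 2)
        np.testing.assert_array_equal(out.conformers[1].coords, confs[1].coords)

    def test_pipeline_order_window_then_cap(self):
        """Documented order: window first, then cap; the result is a subset of
        capping after windowing in any order of application."""
        ens = _toy_ensemble(np.linspace(0, 8, 30))
        a = cap_for_model(energy_window(ens, 5.0), 10)
        b = energy_window(cap_for_model(ens, 10), 5.0)
        ids_a = {tuple(c.coords.ravel()) for c in a.conformers}
        ids_b = {tuple(c.coords.ravel()) for c in b.conformers}
        assert ids_b <= ids_a


class TestFormats:
    def test_xyz_roundtrip(self, tmp_path):
        ens = _toy_ensemble([0.0, 1.5, 4.0])
        path = tmp_path / "e.xyz"
        write_xyz(ens, str(path))
        back = read_xyz(str(path))
        assert len(back) == 1 and len(back[0]) == 3
        np.testing.assert_allclose(
            back[0].conformers[1].coords, ens.conformers[1].coords, atol=1e-7
        )
        assert back[0].conformers[1].rel_energy == pytest.approx(1.5)
        assert back[0].conformers[0].source == "ingested"

    def test_sdf_roundtrip(self, tmp_path):
        ens = generate_ensemble("CCO", n_embed=5, seed=1)
        path = tmp_path / "e.sdf"
        write_sdf([ens], str(path))
        back = read_sdf(str(path))
        assert len(back) == 1
        assert len(back[0]) == len(ens)
        np.testing.assert_allclose(
            back[0].conformers[0].coords, ens.conformers[0].coords, atol=1e-4
        )
        assert back[0].element_symbols == ens.element_symbols
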