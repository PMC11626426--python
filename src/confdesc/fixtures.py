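"""Synthetic fixtures: toy ensembles with known ground truth and cheap labels.

This module makes every pipeline stage testable offline.  It enumerates a
library of small acid/amine SMILES (alkyl, halogenated, aryl substituents) so
moiety mapping is genuinely exercised, builds toy conformer ensembles whose
per-conformer property values follow declared functions of the relative
energy (plus stated Gaussian noise), and provides exactly-computable
surrogate-model training labels.

Ground-truth condensation is evaluated on an independent high-precision path
(50-digit ``decimal`` arithmetic of the Boltzmann weight formula), so
agreement with the production float64 path is a real cross-check, not a
tautology.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import Decimal, getcontext
from typing import Callable

import numpy as np
from rdkit import Chem

from .condense import CondensedDescriptor, PerConformerRecord
from .ensembles import (
    Conformer,
    ConformerEnsemble,
    cap_for_model,
    energy_window,
    generate_ensemble,
)

# ---------------------------------------------------------------------------
# Fixture molecule enumeration
# ---------------------------------------------------------------------------


def _alkyl_fragments(max_carbons: int) -> list[str]:
    """SMILES fragments of all alkyl substituents up to ``max_carbons`` atoms,
    rooted at the attachment carbon."""
    memo: dict[int, set[str]] = {1: {"C"}}
    for n in range(2, max_carbons + 1):
        out: set[str] = set()
        for n_children in (1, 2, 3):
            for parts in _compositions(n - 1, n_children):
                for combo in itertools.product(*[sorted(memo[p]) for p in parts]):
                    combo = sorted(combo)
                    frag = "C" + "".join(f"({c})" for c in combo[:-1]) + combo[-1]
                    out.add(frag)
        memo[n] = out
    return sorted(set().union(*memo.values()))


def _compositions(total: int, k: int):
    if k == 1:
        yield (total,)
        return
    for first in range(1, total - k + 2):
        for rest in _compositions(total - first, k - 1):
            yield (first,) + rest


_HALO_FRAGMENTS = [
    "CF", "CCl", "CBr", "C(F)F", "C(F)(F)F", "CCF", "CCCl", "CCBr",
    "CC(F)F", "CC(F)(F)F", "CCCF", "CCCCl", "C(Cl)Cl", "CC(Cl)Cl",
    "CC(C)F", "CC(C)Cl", "CCC(F)(F)F", "CCCCF",
]
_ARYL_FRAGMENTS = [
    "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "c1ccc(F)cc1", "c1ccc(Cl)cc1",
    "Cc1ccc(C)cc1",
]


def _canonical_unique(smiles_list: list[str]) -> list[str]:
    seen, out = set(), []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can not in seen:
            seen.add(can)
            out.append(can)
    return out


def fixture_smiles(cls: str | None = None, max_carbons: int = 8) -> list[str]:
    """Enumerated mono-functional fixture molecules.

    ``cls`` selects acids, primary amines or secondary amines; ``None``
    concatenates all three (acids first).  Deterministic order.
    """
    alkyl = _alkyl_fragments(max_carbons)
    if cls == "acid":
        frags = alkyl + _HALO_FRAGMENTS + _ARYL_FRAGMENTS
        return _canonical_unique([f"OC(=O){r}" for r in frags])
    if cls == "primary_amine":
        return _canonical_unique([f"N{r}" for r in alkyl + _HALO_FRAGMENTS])
    if cls == "secondary_amine":
        small = [r for r in alkyl if len(r) <= 4]
        return _canonical_unique(
            [f"{a}N{b}" for a in small for b in ["C", "CC", "CCC"]]
        )
    out = []
    for c in ("acid", "primary_amine", "secondary_amine"):
        out += fixture_smiles(c, max_carbons)
    return _canonical_unique(out)


# ---------------------------------------------------------------------------
# Toy ensembles with known condensation ground truth
# ---------------------------------------------------------------------------

PropertyGenerator = Callable[[np.ndarray, np.random.Generator], np.ndarray]


def linear_in_energy(slope: float = 1.0, offset: float = 0.0,
                     noise_sigma: float = 0.0) -> PropertyGenerator:
    """x_i = offset + slope * dE_i (+ N(0, sigma) noise)."""

    def gen(energies: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        x = offset + slope * energies
        if noise_sigma > 0:
            x = x + rng.normal(0.0, noise_sigma, size=len(energies))
        return x

    return gen


def random_uniform(lo: float = -1.0, hi: float = 1.0) -> PropertyGenerator:
    def gen(energies: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(lo, hi, size=len(energies))

    return gen


@dataclass
class FixtureSpec:
    """Recipe for one batch of toy ensembles; same seed, same bytes out."""

    n_molecules: int = 10
    property_generators: dict[str, PropertyGenerator] = field(
        default_factory=lambda: {
            "prop_linear": linear_in_energy(1.0, 0.0),
            "prop_random": random_uniform(),
        }
    )
    energy_scale: float = 2.0  # kcal/mol, exponential draw clipped to [0, 8]
    n_atoms: int = 3
    seed: int = 42


def _dec_condense(values: np.ndarray, energies: np.ndarray,
                  T: float = 298.15) -> CondensedDescriptor:
    """50-digit decimal evaluation of the condensed statistics."""
    getcontext().prec = 50
    RT = Decimal("1.987204e-3") * Decimal(repr(T))
    ws = [(-Decimal(repr(float(e))) / RT).exp() for e in energies]
    z = sum(ws)
    ws = [w / z for w in ws]
    xs = [Decimal(repr(float(v))) for v in values]
    mean = sum(w * x for w, x in zip(ws, xs))
    var = sum(w * (x - mean) ** 2 for w, x in zip(ws, xs))
    low_idx = int(np.argmin(energies))
    return CondensedDescriptor(
        boltz=float(mean),
        boltz_std=float(var.sqrt()),
        min=float(min(xs)),
        max=float(max(xs)),
        low_E=float(xs[low_idx]),
    )


def make_ensemble_fixture(
    n_conformers: int,
    spec: FixtureSpec,
    molecule_id: str = "fixture",
    rng: np.random.Generator | None = None,
    window: float | None = None,
    T: float = 298.15,
) -> tuple[ConformerEnsemble, list[PerConformerRecord], dict[str, CondensedDescriptor]]:
    """Toy ensemble + per-conformer records + independent ground truth.

    Energies are exponential draws (scale ``spec.energy_scale``) clipped to
    [0, 8] kcal/mol and re-zeroed so exactly one conformer sits at 0.  When a
    ``window`` is given, conformers above it are excluded from both the
    records and the ground truth, mirroring the production pipeline order.
    """
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")
    rng = rng or np.random.default_rng(spec.seed)
    e = np.clip(rng.exponential(spec.energy_scale, size=n_conformers), 0.0, 8.0)
    e -= e.min()
    values = {name: gen(e, rng) for name, gen in spec.property_generators.items()}

    keep = np.arange(n_conformers) if window is None else np.nonzero(e <= window)[0]
    e_kept = e[keep]

    conformers = [
        Conformer(coords=rng.normal(size=(spec.n_atoms, 3)), rel_energy=float(ei),
                  source="generated")
        for ei in e_kept
    ]
    ensemble = ConformerEnsemble(
        molecule_id=molecule_id,
        conformers=conformers,
        element_symbols=["C"] * spec.n_atoms,
    )
    records = [
        PerConformerRecord(
            molecule_id=molecule_id,
            conformer_index=int(ci),
            rel_energy=float(e[ci]),
            properties={name: float(values[name][ci]) for name in values},
        )
        for ci in keep
    ]
    truth = {
        name: _dec_condense(values[name][keep], e_kept, T=T) for name in values
    }
    return ensemble, records, truth


# ---------------------------------------------------------------------------
# Exactly-computable surrogate training labels
# ---------------------------------------------------------------------------


def surrogate_labels(
    smiles_list: list[str],
    kind: str,
    seed: int = 42,
    n_embed: int = 10,
    window: float = 5.0,
    cap: int = 20,
) -> np.ndarray:
    """Cheap exactly-computable labels for model-training tests.

    ``heavy_atom_count`` and ``ring_count`` are topological;
    ``mean_pairwise_distance_ensemble_mean`` is the ensemble mean (over the
    windowed, capped generated conformers) of the mean pairwise interatomic
    distance over *all* atoms including hydrogens — the geometry-dependent
    probe that separates 2D from 3D models.
    """
    if kind == "heavy_atom_count":
        return np.array([
            float(Chem.MolFromSmiles(s).GetNumHeavyAtoms()) for s in smiles_list
        ])
    if kind == "ring_count":
        from rdkit.Chem import rdMolDescriptors

        return np.array([
            float(rdMolDescriptors.CalcNumRings(Chem.MolFromSmiles(s)))
            for s in smiles_list
        ])
    if kind == "mean_pairwise_distance_ensemble_mean":
        out = []
        for s in smiles_list:
            ens = cap_for_model(
                energy_window(generate_ensemble(s, n_embed=n_embed, seed=seed),
                              window),
                cap,
            )
            per_conf = []
            for conf in ens.conformers:
                d = np.linalg.norm(
                    conf.coords[:, None, :] - conf.coords[None, :, :], axis=-1
                )
                n = len(conf.coords)
                per_conf.append(d[np.triu_indices(n, k=1)].mean())
            out.append(float(np.mean(per_conf)))
        return np.array(out)
    raise ValueError(f"unknown label kind {kind!r}")


def fixture_ensembles(
    smiles_list: list[str],
    seed: int = 42,
    n_embed: int = 10,
    window: float = 5.0,
    cap: int = 20,
) -> list[ConformerEnsemble]:
    """Generated, windowed, capped ensembles for a list of fixture SMILES."""
    return [
        cap_for_model(
            energy_window(generate_ensemble(s, n_embed=n_embed, seed=seed), window),
            cap,
        )
        for s in smiles_list
    ]
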