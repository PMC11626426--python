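"""End-to-end descriptor pipeline: SMILES -> ensembles -> condensed table.

For each molecule the pipeline maps the conserved moiety, generates and
prunes a conformer ensemble, applies the energy window, computes the
geometric descriptors per conformer (SASA, solvent-accessible volume,
point-charge dipole from Gasteiger charges, buried volume on the conserved
atoms, Sterimol along the moiety axis, nitrogen pyramidalization for amines)
and condenses them into the five ensemble statistics.  Quantum-chemistry
properties (orbital energies, NBO charges, NMR shifts, IR frequencies,
lone-pair terms, polarizability) are never computed here; their schema
columns stay empty unless per-conformer records are ingested and merged.

One bad molecule never aborts a batch: failures are logged and counted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .condense import PerConformerRecord, condense_records, schema
from .ensembles import ConformerEnsemble, dedup, energy_window, generate_ensemble
from .geometry import (
    STERIMOL_RADII,
    VBUR_RADII,
    buried_volume,
    point_charge_dipole,
    pyramidalization,
    sasa_and_volume,
    sterimol,
)
from .moiety import MoietyError, builtin_moiety, map_moiety

log = logging.getLogger(__name__)

_STERIMOL_AXES = {"acid": ("C1", "C4"), "primary_amine": ("N1", "C2")}

_AVERAGED = {"primary_amine": {"H3H4": ("H3", "H4")}}


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; hashed into output metadata."""

    cls: str = "acid"
    n_embed: int = 50
    seed: int = 42
    rmsd_cut: float = 0.5
    window: float = 5.0
    temperature: float = 298.15
    vbur_sphere: float = 3.5
    vbur_grid: float = 0.1
    sasa_probe: float = 1.4
    sasa_points: int = 960
    volume_grid: float = 0.2
    moiety_index: int | None = None

    def validate(self) -> None:
        schema(self.cls)  # raises on unknown class
        if self.n_embed < 1 or self.window < 0 or self.temperature <= 0:
            raise ValueError("invalid config: n_embed >= 1, window >= 0, T > 0")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    table: pd.DataFrame
    records: list[PerConformerRecord]
    n_succeeded: int
    n_failed: int
    failures: dict[str, str]
    config: RunConfig

    def metadata(self) -> dict:
        return {
            "class": self.config.cls,
            "window_kcal_mol": self.config.window,
            "temperature_K": self.config.temperature,
            "config_hash": self.config.config_hash(),
            "n_succeeded": self.n_succeeded,
            "n_failed": self.n_failed,
        }

    def write_csv(self, path: str) -> None:
        self.table.to_csv(path)
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def geometric_records(
    ensemble: ConformerEnsemble,
    cls: str,
    config: RunConfig | None = None,
    select_index: int | None = None,
) -> list[PerConformerRecord]:
    """Per-conformer geometric descriptor records for one windowed ensemble."""
    cfg = config or RunConfig(cls=cls)
    mol = ensemble.mol
    if mol is None:
        raise ValueError("ensemble needs connectivity for geometric descriptors")
    mm = map_moiety(mol, builtin_moiety(cls), ensemble.molecule_id,
                    select_index=select_index)
    symbols = ensemble.element_symbols
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]

    charged = Chem.Mol(mol)
    AllChem.ComputeGasteigerCharges(charged)
    charges = np.array([
        float(a.GetProp("_GasteigerCharge")) for a in charged.GetAtoms()
    ])
    charges = np.nan_to_num(charges, nan=0.0)

    axis = _STERIMOL_AXES.get(cls)
    averaged = _AVERAGED.get(cls, {})
    plain_roles = {
        r: i for r, i in mm.role_to_atom.items()
        if not any(r in members for members in averaged.values())
    }

    records = []
    for ci, conf in enumerate(ensemble.conformers):
        props: dict[str, float] = {}
        sasa, vol = sasa_and_volume(
            conf.coords, symbols, STERIMOL_RADII,
            probe=cfg.sasa_probe, n_points=cfg.sasa_points, grid=cfg.volume_grid,
        )
        props["SASA"] = sasa
        props["SA_volume"] = vol
        props["dipole"] = point_charge_dipole(conf.coords, charges)

        vbur = {
            role: buried_volume(conf.coords, symbols, idx,
                                sphere_r=cfg.vbur_sphere, radii=VBUR_RADII,
                                grid=cfg.vbur_grid)
            for role, idx in mm.role_to_atom.items()
        }
        for role, idx in plain_roles.items():
            props[f"{role}_Vbur"] = vbur[role]
        for col, members in averaged.items():
            vals = [vbur[m] for m in members if m in vbur]
            if vals:
                props[f"{col}_Vbur"] = float(np.mean(vals))

        if axis is not None:
            a_role, f_role = axis
            if a_role in mm.role_to_atom and f_role in mm.role_to_atom:
                st = sterimol(conf.coords, symbols, mm.role_to_atom[a_role],
                              mm.role_to_atom[f_role], STERIMOL_RADII, bonds=bonds,
                              axis_from_role=a_role, axis_to_role=f_role)
                props["Sterimol_L"] = st.L
                props["Sterimol_B1"] = st.B1
                props["Sterimol_B5"] = st.B5

        if cls in ("primary_amine", "secondary_amine"):
            n_idx = mm.role_to_atom["N1"]
            nbrs = [nb.GetIdx() for nb in mol.GetAtomWithIdx(n_idx).GetNeighbors()]
            props["N1_pyramidalization"] = pyramidalization(conf.coords, n_idx, nbrs)

        records.append(PerConformerRecord(
            molecule_id=ensemble.molecule_id,
            conformer_index=ci,
            rel_energy=conf.rel_energy,
            properties=props,
        ))
    return records


def run_pipeline(
    smiles_list: list[str],
    config: RunConfig,
    molecule_ids: list[str] | None = None,
    ingested_records: list[PerConformerRecord] | None = None,
) -> PipelineResult:
    """Full descriptor pipeline with per-molecule error isolation.

    Returns the condensed table over the class schema (QM-only columns empty
    unless matching ``ingested_records`` are supplied), the per-conformer
    records, and success/failure counts.
    """
    config.validate()
    ids = molecule_ids or smiles_list
    if len(ids) != len(smiles_list):
        raise ValueError("molecule_ids must match smiles_list length")

    all_records: list[PerConformerRecord] = []
    failures: dict[str, str] = {}
    for mol_id, smi in zip(ids, smiles_list):
        try:
            ens = generate_ensemble(smi, n_embed=config.n_embed, seed=config.seed,
                                    molecule_id=mol_id)
            ens = energy_window(dedup(ens, config.rmsd_cut), config.window)
            all_records.extend(
                geometric_records(ens, config.cls, config,
                                  select_index=config.moiety_index)
            )
        except (MoietyError, ValueError, RuntimeError) as exc:
            log.warning("molecule %s failed: %s", mol_id, exc)
            failures[mol_id] = str(exc)

    if ingested_records:
        merged: dict[tuple[str, int], PerConformerRecord] = {
            (r.molecule_id, r.conformer_index): r for r in all_records
        }
        for r in ingested_records:
            key = (r.molecule_id, r.conformer_index)
            if key in merged:
                merged[key].properties.update(r.properties)
            else:
                merged[key] = r
        all_records = list(merged.values())

    table = condense_records(all_records, cls=config.cls, T=config.temperature)
    return PipelineResult(
        table=table,
        records=all_records,
        n_succeeded=len(ids) - len(failures),
        n_failed=len(failures),
        failures=failures,
        config=config,
    )
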