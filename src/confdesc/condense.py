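"""Condense per-conformer property values into five ensemble statistics.

For each property x over a windowed conformer ensemble with relative energies
dE_i (kcal/mol), the condensed descriptors are: the Boltzmann-weighted mean
x_bar = sum_i w_i x_i and standard deviation sqrt(sum_i w_i (x_i - x_bar)^2)
with w_i = exp(-dE_i/RT)/Z, the minimum and maximum property values over the
window, and the value at the lowest-energy conformer (low_E).  Together these
capture both the aggregate accessible conformations and the extremes a
molecule can reach within the energetic window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987204e-3

#: Condensed statistic names, in output order.
STATISTICS = ("boltz", "boltz_std", "min", "max", "low_E")


@dataclass
class PerConformerRecord:
    """Named property values for one conformer of one molecule.

    Units ride with the property definition (eV or hartree for orbital
    energies as ingested, e for charges, ppm for shifts, cm^-1 for IR
    frequencies, angstrom-based units for geometric descriptors, Debye for
    dipoles).  Missing values are explicit ``None``/NaN, never silent zeros.
    """

    molecule_id: str
    conformer_index: int
    rel_energy: float
    properties: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CondensedDescriptor:
    boltz: float
    boltz_std: float
    min: float
    max: float
    low_E: float

    def as_dict(self) -> dict[str, float]:
        return {s: getattr(self, s) for s in STATISTICS}


def boltzmann_weights(rel_energies, T: float = 298.15) -> np.ndarray:
    """Normalized Boltzmann populations w_i = exp(-dE_i/RT)/Z.

    ``rel_energies`` are kcal/mol relative to the ensemble minimum (>= 0 with
    at least one zero).
    """
    e = np.asarray(rel_energies, dtype=float)
    if e.size == 0:
        raise ValueError("empty energy list")
    if e.min() < -1e-9:
        raise ValueError("relative energies must be >= 0 (re-zero to the minimum)")
    if T <= 0:
        raise ValueError("temperature must be positive")
    w = np.exp(-e / (R_KCAL * T))
    return w / w.sum()


def condense(values, rel_energies, T: float = 298.15) -> CondensedDescriptor:
    """All five condensed statistics of one property over a windowed ensemble.

    low_E is the value at the first conformer with relative energy zero
    (first-in-order tie break).
    """
    x = np.asarray(values, dtype=float)
    e = np.asarray(rel_energies, dtype=float)
    if x.shape != e.shape:
        raise ValueError("values and rel_energies must have equal length")
    if np.any(np.isnan(x)):
        raise ValueError("missing per-conformer values; drop or fill before condensing")
    w = boltzmann_weights(e, T=T)
    mean = float(w @ x)
    std = float(math.sqrt(max(0.0, w @ (x - mean) ** 2)))
    low_idx = int(np.argmin(e))  # first minimal energy wins on ties
    return CondensedDescriptor(
        boltz=mean,
        boltz_std=std,
        min=float(x.min()),
        max=float(x.max()),
        low_E=float(x[low_idx]),
    )


# ---------------------------------------------------------------------------
# Per-class property schemas
# ---------------------------------------------------------------------------

_MOLECULE_LEVEL = ["HOMO", "LUMO", "polarizability", "dipole", "SASA", "SA_volume"]
_ATOM_PROPS = ["NBO", "NMR", "Vbur"]


def schema(cls: str) -> list[str]:
    """Ordered property list collected for a substrate class.

    Molecule-level properties are shared; atom-level NBO charge, NMR shift and
    buried volume columns are emitted per conserved atom (with the two primary
    amine hydrogens averaged into a single H3H4 column); acids additionally
    carry Sterimol values on the C1->C4 axis and the carbonyl IR stretch,
    amines the nitrogen descriptors (pyramidalization, lone-pair energy and
    occupancy).  Secondary amines have no Sterimol entries.
    """
    if cls == "acid":
        atoms = ["C1", "O2", "O3", "C4", "H5"]
        extra = ["Sterimol_L", "Sterimol_B1", "Sterimol_B5", "IR_CO_stretch"]
    elif cls == "primary_amine":
        atoms = ["N1", "C2", "H3H4"]
        extra = [
            "N1_pyramidalization", "N1_LP_energy", "N1_LP_occupancy",
            "Sterimol_L", "Sterimol_B1", "Sterimol_B5",
        ]
    elif cls == "secondary_amine":
        atoms = ["N1", "H4"]
        extra = ["N1_pyramidalization", "N1_LP_energy", "N1_LP_occupancy"]
    else:
        raise ValueError(
            f"unknown class {cls!r}; expected acid, primary_amine or secondary_amine"
        )
    props = list(_MOLECULE_LEVEL)
    props += [f"{a}_{p}" for a in atoms for p in _ATOM_PROPS]
    props += extra
    return props


def condense_records(
    records: list[PerConformerRecord],
    cls: str | None = None,
    properties: list[str] | None = None,
    T: float = 298.15,
) -> pd.DataFrame:
    """Build a molecule x (property, statistic) condensed descriptor table.

    Column order is schema order x (boltz, boltz_std, min, max, low_E) with
    headers '<property>_<stat>'.  A property missing on any conformer of a
    molecule yields empty cells for that molecule (logged), never imputation.
    """
    if properties is None:
        properties = schema(cls) if cls is not None else sorted(
            {p for r in records for p in r.properties}
        )
    by_mol: dict[str, list[PerConformerRecord]] = {}
    for r in records:
        by_mol.setdefault(r.molecule_id, []).append(r)

    rows = {}
    missing_count: dict[str, int] = {}
    for mol_id, recs in by_mol.items():
        recs = sorted(recs, key=lambda r: r.conformer_index)
        energies = np.array([r.rel_energy for r in recs], float)
        row: dict[str, float] = {}
        for prop in properties:
            vals = [r.properties.get(prop) for r in recs]
            if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
                missing_count[prop] = missing_count.get(prop, 0) + 1
                for stat in STATISTICS:
                    row[f"{prop}_{stat}"] = np.nan
                continue
            cd = condense(np.array(vals, float), energies, T=T)
            for stat, v in cd.as_dict().items():
                row[f"{prop}_{stat}"] = v
        rows[mol_id] = row

    for prop, cnt in missing_count.items():
        log.warning("property %s missing for %d molecule(s); cells left empty "
                    "(never imputed)", prop, cnt)
    columns = [f"{p}_{s}" for p in properties for s in STATISTICS]
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(columns=columns)
    df.index.name = "molecule_id"
    return df
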