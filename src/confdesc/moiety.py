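"""Locate the conserved reactive moiety and name its atoms by role.

Atom/bond properties are tabulated only for a fixed set of conserved atoms of
the functional group: for carboxylic acids the (R)3-C4-C1(O2)(O3)H5 atoms, for
primary alkyl amines N1/C2 plus the two amine hydrogens H3/H4 (whose atom
properties are symmetry-equivalent and reported as a single average), and for
secondary alkyl amines N1/H4 only — the two carbon neighbors of a secondary
amine nitrogen cannot be distinguished, so no property is collected on them.

Role names carry the conventional 1-based superscripts (C1, O2, ...); all atom
indices handled by this module are 0-based RDKit indices on the molecule with
explicit hydrogens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from rdkit import Chem


class MoietyError(ValueError):
    """Base class for moiety-mapping failures."""


class MoietyNotFound(MoietyError):
    """The SMARTS pattern matched no substructure of the molecule."""


class AmbiguousMoiety(MoietyError):
    """More than one substructure match and no selection index given."""

    def __init__(self, message: str, match_count: int):
        super().__init__(message)
        self.match_count = match_count


@dataclass(frozen=True)
class MoietySpec:
    """Definition of a conserved moiety: pattern, roles and symmetry rules.

    ``averaged_groups`` lists sets of roles whose atom properties are reported
    as a single mean column (e.g. the two amine hydrogens); ``excluded_roles``
    are matched atoms on which no property is collected at all.
    """

    name: str
    smarts: str
    role_labels: tuple[str, ...]
    averaged_groups: tuple[frozenset[str], ...] = ()
    excluded_roles: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        roles = set(self.role_labels)
        averaged = set().union(*self.averaged_groups) if self.averaged_groups else set()
        if not averaged <= roles:
            raise ValueError("averaged_groups must be subsets of role_labels")
        if not self.excluded_roles <= roles:
            raise ValueError("excluded_roles must be a subset of role_labels")
        if averaged & self.excluded_roles:
            raise ValueError("averaged_groups and excluded_roles must be disjoint")


@dataclass
class MoietyMap:
    """Resolved role -> atom-index map for one molecule."""

    molecule_id: str
    role_to_atom: dict[str, int]
    match_count: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "molecule_id": self.molecule_id,
                "role_to_atom": self.role_to_atom,
                "match_count": self.match_count,
            }
        )


_BUILTINS: dict[str, MoietySpec] = {
    # SMARTS atom order: C1 (carboxyl C), O2 (carbonyl O), O3 (hydroxyl O).
    # C4 (the acyl carbon of R) and H5 (hydroxyl H) are resolved from the
    # match by neighborhood expansion.
    "acid": MoietySpec(
        name="acid",
        smarts="[CX3](=[OX1])[OX2H1]",
        role_labels=("C1", "O2", "O3", "C4", "H5"),
    ),
    # N1, C2 from the SMARTS; H3/H4 are the two amine hydrogens, averaged.
    "primary_amine": MoietySpec(
        name="primary_amine",
        smarts="[NX3;H2][CX4]",
        role_labels=("N1", "C2", "H3", "H4"),
        averaged_groups=(frozenset({"H3", "H4"}),),
    ),
    # Secondary amines: only N1 and the amine hydrogen H4 carry properties;
    # the two symmetric carbon neighbors are excluded entirely.
    "secondary_amine": MoietySpec(
        name="secondary_amine",
        smarts="[NX3;H1]([CX4])[CX4]",
        role_labels=("N1", "H4"),
    ),
}


def builtin_moiety(name: str) -> MoietySpec:
    """Return the built-in spec for ``acid``/``primary_amine``/``secondary_amine``."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise MoietyError(
            f"unknown moiety {name!r}; valid names: {sorted(_BUILTINS)}"
        ) from None


def _expand_acid(mol: Chem.Mol, match: tuple[int, ...]) -> dict[str, int | None]:
    c1, o2, o3 = match
    roles: dict[str, int | None] = {"C1": c1, "O2": o2, "O3": o3}
    # C4: the unique heavy-atom neighbor of C1 that is not O2/O3.  Formic acid
    # has none; its C4-dependent properties are simply missing downstream.
    c4 = None
    for nb in mol.GetAtomWithIdx(c1).GetNeighbors():
        if nb.GetIdx() not in (o2, o3) and nb.GetAtomicNum() > 1:
            c4 = nb.GetIdx()
    roles["C4"] = c4
    h5 = [nb.GetIdx() for nb in mol.GetAtomWithIdx(o3).GetNeighbors()
          if nb.GetAtomicNum() == 1]
    roles["H5"] = h5[0] if h5 else None
    return roles


def _expand_primary_amine(mol: Chem.Mol, match: tuple[int, ...]) -> dict[str, int | None]:
    n1, c2 = match
    hs = sorted(nb.GetIdx() for nb in mol.GetAtomWithIdx(n1).GetNeighbors()
                if nb.GetAtomicNum() == 1)
    if len(hs) != 2:
        raise MoietyError("primary amine nitrogen must carry exactly two hydrogens "
                          "(add explicit hydrogens before mapping)")
    return {"N1": n1, "C2": c2, "H3": hs[0], "H4": hs[1]}


def _expand_secondary_amine(mol: Chem.Mol, match: tuple[int, ...]) -> dict[str, int | None]:
    n1 = match[0]
    hs = [nb.GetIdx() for nb in mol.GetAtomWithIdx(n1).GetNeighbors()
          if nb.GetAtomicNum() == 1]
    if len(hs) != 1:
        raise MoietyError("secondary amine nitrogen must carry exactly one hydrogen "
                          "(add explicit hydrogens before mapping)")
    return {"N1": n1, "H4": hs[0]}


_EXPANDERS = {
    "acid": _expand_acid,
    "primary_amine": _expand_primary_amine,
    "secondary_amine": _expand_secondary_amine,
}


def map_moiety(
    mol: Chem.Mol,
    spec: MoietySpec,
    molecule_id: str = "",
    select_index: int | None = None,
) -> MoietyMap:
    """Map the spec's roles onto atom indices of ``mol`` (explicit hydrogens).

    Raises :class:`MoietyNotFound` on zero matches and
    :class:`AmbiguousMoiety` on multiple matches unless ``select_index`` picks
    one; matches are ordered deterministically by their first (C1/N1) atom
    index, so ``select_index=0`` selects the lowest-index match.
    """
    if mol is None:
        raise MoietyError("molecule is None (SMILES failed to parse?)")
    if not any(a.GetAtomicNum() == 1 for a in mol.GetAtoms()) and any(
        a.GetTotalNumHs() > 0 for a in mol.GetAtoms()
    ):
        mol = Chem.AddHs(mol)

    patt = Chem.MolFromSmarts(spec.smarts)
    matches = sorted(mol.GetSubstructMatches(patt), key=lambda m: m[0])
    if not matches:
        raise MoietyNotFound(
            f"moiety {spec.name!r} not found in molecule {molecule_id or '<unnamed>'}"
        )
    if len(matches) > 1 and select_index is None:
        raise AmbiguousMoiety(
            f"moiety {spec.name!r} matched {len(matches)} times in "
            f"{molecule_id or '<unnamed>'}; pass select_index to choose one",
            match_count=len(matches),
        )
    match = matches[select_index or 0]

    expander = _EXPANDERS.get(spec.name)
    if expander is not None:
        roles = expander(mol, match)
    else:  # custom spec: roles map positionally onto the SMARTS atoms
        if len(spec.role_labels) != len(match):
            raise MoietyError(
                f"custom spec has {len(spec.role_labels)} roles but SMARTS "
                f"matched {len(match)} atoms"
            )
        roles = dict(zip(spec.role_labels, match))

    role_to_atom = {r: i for r, i in roles.items() if i is not None}
    return MoietyMap(
        molecule_id=molecule_id,
        role_to_atom=role_to_atom,
        match_count=len(matches),
    )


def mol_with_hs(smiles: str) -> Chem.Mol:
    """Parse SMILES and add explicit hydrogens, raising on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoietyError(f"SMILES failed to parse: {smiles!r}")
    return Chem.AddHs(mol)
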