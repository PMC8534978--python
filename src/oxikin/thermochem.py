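"""Homolytic bond-dissociation enthalpies and frontier-orbital gaps.

A homolytic BDE is computed from tabulated species enthalpies as

    BDE = E(radical) + E(H atom) - E(parent)

with every term converted to kJ/mol first. For a phenolic antioxidant the
lower the O-H BDE, the better the hydrogen-atom donor; for a lipid the
lower the allylic C-H BDE, the more autoxidation-prone the site. This
module only does the arithmetic on given energies — it never runs or
parses electronic-structure calculations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .constants import HARTREE_TO_KJ_PER_MOL


class EnergyUnit(str, Enum):
    HARTREE = "hartree"
    KJ_PER_MOL = "kJ_per_mol"


class SpeciesRole(str, Enum):
    PARENT = "parent"
    RADICAL = "radical"
    HYDROGEN_ATOM = "hydrogen_atom"
    ORBITAL_HOMO = "orbital_homo"
    ORBITAL_LUMO = "orbital_lumo"


@dataclass(frozen=True)
class SpeciesEnergy:
    """One species' enthalpy/energy with its unit and role in a homolysis."""

    label: str
    energy: float
    unit: EnergyUnit = EnergyUnit.KJ_PER_MOL
    role: SpeciesRole = SpeciesRole.PARENT

    def __post_init__(self) -> None:
        # float("nan") != itself; also rejects inf
        import math

        if not math.isfinite(self.energy):
            raise ValueError(f"species {self.label!r}: energy must be finite")
        # coerce plain strings from CSV input
        object.__setattr__(self, "unit", EnergyUnit(self.unit))
        object.__setattr__(self, "role", SpeciesRole(self.role))

    def to_kj_per_mol(self) -> float:
        return convert_energy(self.energy, self.unit, EnergyUnit.KJ_PER_MOL)


@dataclass(frozen=True)
class BDERecord:
    """A homolytic bond-dissociation enthalpy in kJ/mol."""

    bond_label: str
    bde_kj_mol: float
    parent_label: str
    radical_label: str


def convert_energy(value: float, from_unit: EnergyUnit | str, to_unit: EnergyUnit | str) -> float:
    """Convert an energy between hartree and kJ/mol.

    Identity when units are equal; otherwise multiplies or divides by
    :data:`oxikin.constants.HARTREE_TO_KJ_PER_MOL`.
    """
    try:
        f, t = EnergyUnit(from_unit), EnergyUnit(to_unit)
    except ValueError as exc:
        raise ValueError(f"unknown energy unit: {exc}") from None
    if f == t:
        return value
    if f == EnergyUnit.HARTREE:
        return value * HARTREE_TO_KJ_PER_MOL
    return value / HARTREE_TO_KJ_PER_MOL


def bde_homolytic(
    parent: SpeciesEnergy,
    radical: SpeciesEnergy,
    hydrogen: SpeciesEnergy,
    bond_label: str | None = None,
) -> BDERecord:
    """BDE = E(radical) + E(H) - E(parent), all in kJ/mol.

    Roles are checked but only warned about; a negative or zero BDE (not
    physical for homolysis of a stable parent) also warns rather than fails.
    """
    expected = [
        (parent, SpeciesRole.PARENT),
        (radical, SpeciesRole.RADICAL),
        (hydrogen, SpeciesRole.HYDROGEN_ATOM),
    ]
    for sp, role in expected:
        if sp.role != role:
            warnings.warn(
                f"species {sp.label!r} has role {sp.role.value!r}, expected {role.value!r}",
                stacklevel=2,
            )
    bde = radical.to_kj_per_mol() + hydrogen.to_kj_per_mol() - parent.to_kj_per_mol()
    if bde <= 0:
        warnings.warn(
            f"non-positive BDE ({bde:.2f} kJ/mol) for {radical.label!r}: "
            "homolysis of a stable parent should cost energy",
            stacklevel=2,
        )
    return BDERecord(
        bond_label=bond_label or radical.label,
        bde_kj_mol=bde,
        parent_label=parent.label,
        radical_label=radical.label,
    )


def frontier_gap(homo: SpeciesEnergy, lumo: SpeciesEnergy) -> float:
    """Frontier-orbital gap E(LUMO) - E(HOMO) in kJ/mol.

    A smaller gap indicates a more reactive (less stable) species; the
    interpretation is the caller's — only the subtraction is done here.
    """
    return lumo.to_kj_per_mol() - homo.to_kj_per_mol()


def rank_sites(records: list[BDERecord]) -> list[BDERecord]:
    """Order homolysis sites by reactivity: ascending BDE, ties by label.

    The first element is the most easily broken bond (the most active
    H-donation or H-abstraction site).
    """
    if not records:
        raise ValueError("rank_sites requires at least one BDE record")
    return sorted(records, key=lambda r: (r.bde_kj_mol, r.bond_label))


def bde_table(
    species: pd.DataFrame,
    parent_label: str,
    hydrogen_label: str,
) -> pd.DataFrame:
    """Compute BDEs for every radical in a species table against one parent.

    ``species`` needs columns label, energy, unit, role. The parent and
    hydrogen rows are selected by label; every row with role ``radical``
    becomes one BDE record. Returns a DataFrame sorted by ascending BDE.
    """
    def pick(label: str) -> SpeciesEnergy:
        rows = species[species["label"] == label]
        if rows.empty:
            raise ValueError(f"no species labelled {label!r} in table")
        r = rows.iloc[0]
        return SpeciesEnergy(r["label"], float(r["energy"]), r["unit"], r["role"])

    parent = pick(parent_label)
    hydrogen = pick(hydrogen_label)
    records = []
    for _, r in species[species["role"] == SpeciesRole.RADICAL.value].iterrows():
        rad = SpeciesEnergy(r["label"], float(r["energy"]), r["unit"], r["role"])
        if rad.unit != parent.unit:
            # mixed-unit tables are fine per species, but a radical paired
            # with a parent in another unit usually means a label mix-up
            continue
        records.append(bde_homolytic(parent, rad, hydrogen))
    ranked = rank_sites(records)
    return pd.DataFrame(
        {
            "bond_label": [r.bond_label for r in ranked],
            "parent_label": [r.parent_label for r in ranked],
            "radical_label": [r.radical_label for r in ranked],
            "bde_kj_mol": [r.bde_kj_mol for r in ranked],
        }
    )
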