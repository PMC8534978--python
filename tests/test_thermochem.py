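"""Bond-dissociation enthalpy arithmetic and unit handling."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oxikin import datasets
from oxikin.constants import HARTREE_TO_KJ_PER_MOL
from oxikin.thermochem import (
    BDERecord,
    EnergyUnit,
    SpeciesEnergy,
    bde_homolytic,
    bde_table,
    convert_energy,
    frontier_gap,
    rank_sites,
)

finite = st.floats(min_value=-1e7, max_value=1e7, allow_nan=False)


class TestConvertEnergy:
    def test_identity(self):
        assert convert_energy(1.0, "hartree", "hartree") == 1.0

    def test_hartree_to_kj(self):
        assert convert_energy(1.0, "hartree", "kJ_per_mol") == pytest.approx(2625.4996)

    def test_published_allylic_difference(self):
        # the energy gap behind the weaker allylic C-H site, in kJ/mol
        assert convert_energy(0.134801, "hartree", "kJ_per_mol") == pytest.approx(
            353.92, abs=0.01
        )

    @given(finite)
    def test_round_trip_is_identity(self, x):
        back = convert_energy(
            convert_energy(x, EnergyUnit.HARTREE, EnergyUnit.KJ_PER_MOL),
            EnergyUnit.KJ_PER_MOL,
            EnergyUnit.HARTREE,
        )
        assert back == pytest.approx(x, rel=1e-9, abs=1e-12)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            convert_energy(1.0, "eV", "hartree")


# the four published homolysis sites: (parent E, radical E, H E, unit, expected BDE)
PUBLISHED_BDES = [
    ("O15-H", -2836114.23, -2834498.68, -1312.28, "kJ_per_mol", 303.27),
    ("O18-H", -2836114.23, -2834506.32, -1312.28, "kJ_per_mol", 295.63),
    ("C8-H", -856.390, -855.757199, -0.498, "hartree", 353.92),
    ("C11-H", -856.390, -855.757275, -0.498, "hartree", 353.72),
]


class TestBDEHomolytic:
    @pytest.mark.parametrize("bond,ep,er,eh,unit,expected", PUBLISHED_BDES)
    def test_published_sites(self, bond, ep, er, eh, unit, expected):
        rec = bde_homolytic(
            SpeciesEnergy("parent", ep, unit, "parent"),
            SpeciesEnergy("radical", er, unit, "radical"),
            SpeciesEnergy("H", eh, unit, "hydrogen_atom"),
            bond_label=bond,
        )
        assert rec.bde_kj_mol == pytest.approx(expected, abs=0.01)

    def test_unit_invariance(self):
        """Expressing the same energies in hartree or kJ/mol gives the same BDE."""
        kj = [-2836114.23, -2834498.68, -1312.28]
        ha = [e / HARTREE_TO_KJ_PER_MOL for e in kj]
        roles = ["parent", "radical", "hydrogen_atom"]
        rec_kj = bde_homolytic(*[
            SpeciesEnergy(r, e, "kJ_per_mol", r) for e, r in zip(kj, roles)])
        rec_ha = bde_homolytic(*[
            SpeciesEnergy(r, e, "hartree", r) for e, r in zip(ha, roles)])
        assert rec_ha.bde_kj_mol == pytest.approx(rec_kj.bde_kj_mol, abs=0.01)

    def test_energy_conservation_zero_warns(self):
        with pytest.warns(UserWarning, match="non-positive BDE"):
            rec = bde_homolytic(
                SpeciesEnergy("p", -10.0, "kJ_per_mol", "parent"),
                SpeciesEnergy("r", -7.0, "kJ_per_mol", "radical"),
                SpeciesEnergy("h", -3.0, "kJ_per_mol", "hydrogen_atom"),
            )
        assert rec.bde_kj_mol == pytest.approx(0.0, abs=1e-12)

    def test_role_mismatch_warns(self):
        with pytest.warns(UserWarning, match="role"):
            bde_homolytic(
                SpeciesEnergy("p", -10.0, "kJ_per_mol", "radical"),
                SpeciesEnergy("r", -5.0, "kJ_per_mol", "radical"),
                SpeciesEnergy("h", -3.0, "kJ_per_mol", "hydrogen_atom"),
            )

    def test_non_finite_energy_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            SpeciesEnergy("bad", float("nan"), "hartree", "parent")


class TestFrontierGap:
    def test_subtraction(self):
        homo = SpeciesEnergy("homo", -500.0, "kJ_per_mol", "orbital_homo")
        lumo = SpeciesEnergy("lumo", 25.21, "kJ_per_mol", "orbital_lumo")
        assert frontier_gap(homo, lumo) == pytest.approx(525.21)

    def test_degenerate_orbitals_give_zero(self):
        e = SpeciesEnergy("x", -1.0, "hartree", "orbital_homo")
        assert frontier_gap(e, e) == 0.0

    def test_hartree_inputs(self):
        homo = SpeciesEnergy("homo", -0.2, "hartree", "orbital_homo")
        lumo = SpeciesEnergy("lumo", 0.0, "hartree", "orbital_lumo")
        assert frontier_gap(homo, lumo) == pytest.approx(525.10, abs=0.01)


class TestRankSites:
    def test_most_active_site_first(self):
        """The weaker phenolic O-H (O18) outranks O15 as the H-donation site."""
        recs = [
            BDERecord("O(15)-H", 303.27, "CA", "r15"),
            BDERecord("O(18)-H", 295.63, "CA", "r18"),
        ]
        assert [r.bond_label for r in rank_sites(recs)] == ["O(18)-H", "O(15)-H"]

    def test_single_record(self):
        rec = BDERecord("X-H", 100.0, "p", "r")
        assert rank_sites([rec]) == [rec]

    def test_ties_break_lexicographically(self):
        recs = [BDERecord("b", 1.0, "p", "r"), BDERecord("a", 1.0, "p", "r")]
        assert [r.bond_label for r in rank_sites(recs)] == ["a", "b"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_sites([])

    @given(st.lists(st.floats(min_value=0.1, max_value=1e3), min_size=1, max_size=8))
    def test_permutation_with_nondecreasing_bde(self, bdes):
        recs = [BDERecord(f"b{i}", v, "p", f"r{i}") for i, v in enumerate(bdes)]
        ranked = rank_sites(recs)
        assert sorted(r.bond_label for r in ranked) == sorted(r.bond_label for r in recs)
        assert all(a.bde_kj_mol <= b.bde_kj_mol for a, b in zip(ranked, ranked[1:]))


class TestBDETable:
    def test_packaged_reference_energies(self):
        sp = datasets.species_energies()
        ca = bde_table(sp, "CA", "H-atom")
        assert ca["bde_kj_mol"].tolist() == pytest.approx([295.63, 303.27], abs=0.01)
        oa = bde_table(sp, "OA", "H-atom-hartree")
        assert oa["bde_kj_mol"].tolist() == pytest.approx([353.72, 353.92], abs=0.01)

    def test_missing_label_rejected(self):
        sp = datasets.species_energies()
        with pytest.raises(ValueError, match="no species"):
            bde_table(sp, "nonexistent", "H-atom")
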