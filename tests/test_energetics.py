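"""LJ/Coulomb closed forms, contact enumeration, and aggregation."""
import dataclasses
import math

import numpy as np
import pytest

from hotforge.energetics import (
    COULOMB_K, DielectricModel, SCREENED, VACUUM,
    enumerate_contacts, pair_energy, residue_pair_table,
)
from hotforge.errors import ParameterizationError

from conftest import make_atom


class TestPairEnergy:
    def test_lj_minimum_depth_is_minus_epsilon(self):
        r = 2 ** (1 / 6) * 3.4
        e_lj, e_coul = pair_energy(0, 0, 3.4, 3.4, 0.2, 0.2, r, VACUUM)
        assert e_lj == pytest.approx(-0.2, abs=1e-12)
        assert e_coul == 0.0

    def test_lj_zero_crossing_at_sigma(self):
        e_lj, _ = pair_energy(0, 0, 3.4, 3.4, 0.2, 0.2, 3.4, VACUUM)
        assert e_lj == pytest.approx(0.0, abs=1e-12)

    def test_vacuum_coulomb_hand_value(self):
        _, e_coul = pair_energy(0.5, -0.5, 3.4, 3.4, 0.0, 0.0, 3.0, VACUUM)
        assert e_coul == pytest.approx(COULOMB_K * -0.25 / 3.0, abs=1e-9)
        assert e_coul == pytest.approx(-27.6720, abs=1e-4)

    def test_screened_coulomb_hand_value(self):
        _, e_coul = pair_energy(0.5, -0.5, 3.4, 3.4, 0.0, 0.0, 3.0, SCREENED)
        assert e_coul == pytest.approx(COULOMB_K * -0.25 / 9.0, abs=1e-9)
        assert e_coul == pytest.approx(-9.2240, abs=1e-4)

    def test_screening_factor_scales_inverse(self):
        _, e1 = pair_energy(0.5, -0.5, 3.4, 3.4, 0, 0, 3.0, DielectricModel("screened", 4.0))
        _, e0 = pair_energy(0.5, -0.5, 3.4, 3.4, 0, 0, 3.0, SCREENED)
        assert e1 == pytest.approx(e0 / 4.0)

    def test_lorentz_berthelot_combination(self):
        # sigma_ij arithmetic mean: zero crossing at (3.0 + 3.8) / 2
        e_lj, _ = pair_energy(0, 0, 3.0, 3.8, 0.3, 0.3, 3.4, VACUUM)
        assert e_lj == pytest.approx(0.0, abs=1e-12)
        # eps_ij geometric mean: well depth sqrt(0.1 * 0.4)
        sig = 3.4
        e_lj, _ = pair_energy(0, 0, sig, sig, 0.1, 0.4, 2 ** (1 / 6) * sig, VACUUM)
        assert e_lj == pytest.approx(-0.2, abs=1e-12)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            pair_energy(0, 0, 3.4, 3.4, 0.1, 0.1, 0.0, VACUUM)

    def test_decay_to_zero_at_long_range(self):
        e_lj, e_scr = pair_energy(0.05, 0.05, 3.4, 3.4, 0.2, 0.2, 1e3, SCREENED)
        assert abs(e_lj) < 1e-6
        assert abs(e_scr) < 1e-6
        # vacuum Coulomb follows the 1/r tail exactly
        _, e_near = pair_energy(0.5, 0.5, 3.4, 3.4, 0.2, 0.2, 10.0, VACUUM)
        _, e_far = pair_energy(0.5, 0.5, 3.4, 3.4, 0.2, 0.2, 1e3, VACUUM)
        assert e_far == pytest.approx(e_near / 100.0, rel=1e-12)


def _pair_at(distance, cutoff=4.5, dielectric=SCREENED):
    rec = [make_atom(serial=1, chain="A", res_seq=1, pos=(0, 0, 0), charge=0.1)]
    lig = [make_atom(serial=2, chain="B", res_seq=1, pos=(distance, 0, 0), charge=-0.1)]
    return enumerate_contacts(rec, lig, cutoff, dielectric)


class TestEnumerateContacts:
    def test_cutoff_semantics(self):
        assert len(_pair_at(4.4)) == 1
        assert len(_pair_at(4.6)) == 0
        assert len(_pair_at(4.5)) == 1  # inclusive

    def test_complete_bipartite_count(self):
        rec = [make_atom(serial=i, chain="A", res_seq=i, pos=(0, 0, i)) for i in range(3)]
        lig = [make_atom(serial=10 + j, chain="B", res_seq=j, pos=(2, 0, j)) for j in range(2)]
        contacts = enumerate_contacts(rec, lig, 10.0)
        assert len(contacts) == 6
        # deterministic ordering: receptor index then ligand index
        assert [(c.atom_i, c.atom_j) for c in contacts] == [
            (0, 0), (0, 1), (1, 0), (1, 1), (2, 0), (2, 1)]

    def test_matches_brute_force_double_loop(self, salt_bridge_dimer):
        from hotforge.forcefield import assign_parameters, fold_hydrogen_charges
        from hotforge.structure_io import InterfaceSpec, select_interface

        model = fold_hydrogen_charges(assign_parameters(salt_bridge_dimer))
        rec, lig = select_interface(model, InterfaceSpec(frozenset("A"), frozenset("B")))
        for diel in (VACUUM, SCREENED):
            contacts = enumerate_contacts(rec, lig, 4.5, diel)
            expected = {}
            for i, a in enumerate(rec):
                for j, b in enumerate(lig):
                    r = float(np.linalg.norm(a.position - b.position))
                    if r <= 4.5:
                        expected[(i, j)] = pair_energy(
                            a.partial_charge, b.partial_charge,
                            a.lj_sigma, b.lj_sigma, a.lj_epsilon, b.lj_epsilon, r, diel)
            assert {(c.atom_i, c.atom_j) for c in contacts} == set(expected)
            for c in contacts:
                e_lj, e_coul = expected[(c.atom_i, c.atom_j)]
                assert c.e_lj == pytest.approx(e_lj, abs=1e-9)
                assert c.e_coul == pytest.approx(e_coul, abs=1e-9)

    def test_symmetry_under_role_swap(self):
        rec = [make_atom(serial=i, chain="A", res_seq=i, pos=(0, 0.3 * i, 0), charge=0.2)
               for i in range(4)]
        lig = [make_atom(serial=9 + j, chain="B", res_seq=j, pos=(3, 0, 0.4 * j), charge=-0.1)
               for j in range(3)]
        fwd = enumerate_contacts(rec, lig, 6.0)
        rev = enumerate_contacts(lig, rec, 6.0)
        fwd_set = {(c.atom_i, c.atom_j, round(c.e_total, 12)) for c in fwd}
        rev_set = {(c.atom_j, c.atom_i, round(c.e_total, 12)) for c in rev}
        assert fwd_set == rev_set

    def test_cutoff_monotonicity(self, salt_bridge_dimer):
        from hotforge.forcefield import assign_parameters, fold_hydrogen_charges
        from hotforge.structure_io import InterfaceSpec, select_interface

        model = fold_hydrogen_charges(assign_parameters(salt_bridge_dimer))
        rec, lig = select_interface(model, InterfaceSpec(frozenset("A"), frozenset("B")))
        small = {(c.atom_i, c.atom_j) for c in enumerate_contacts(rec, lig, 4.0)}
        large = {(c.atom_i, c.atom_j) for c in enumerate_contacts(rec, lig, 6.0)}
        assert small <= large

    def test_infinite_cutoff_equals_all_pairs(self):
        rec = [make_atom(serial=i, chain="A", res_seq=i, pos=(0, 0, 7.0 * i)) for i in range(5)]
        lig = [make_atom(serial=9 + j, chain="B", res_seq=j, pos=(30, 0, 0)) for j in range(4)]
        contacts = enumerate_contacts(rec, lig, math.inf)
        assert len(contacts) == 20

    def test_unparameterized_atom_raises(self):
        bare = make_atom(serial=1, chain="A")
        bare.partial_charge = None
        lig = [make_atom(serial=2, chain="B", pos=(1, 0, 0))]
        with pytest.raises(ParameterizationError):
            enumerate_contacts([bare], lig, 4.5)


class TestResiduePairTable:
    def test_empty(self):
        table = residue_pair_table([])
        assert len(table) == 0
        assert "sum_e_total" in table.columns

    def test_same_residue_pair_aggregates(self):
        contacts = enumerate_contacts(
            [make_atom(serial=1, chain="A", res_seq=1, pos=(0, 0, 0), charge=0.3),
             make_atom(serial=2, chain="A", res_seq=1, pos=(0, 0, 1), charge=0.3)],
            [make_atom(serial=3, chain="B", res_seq=9, pos=(3, 0, 0), charge=-0.3)],
            10.0,
        )
        table = residue_pair_table(contacts)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.n_atom_pairs == 2
        assert row.min_distance_A == pytest.approx(min(c.distance for c in contacts))
        assert row.sum_e_total == pytest.approx(sum(c.e_total for c in contacts))

    def test_energy_conservation_under_aggregation(self, salt_bridge_dimer):
        from hotforge.forcefield import assign_parameters, fold_hydrogen_charges
        from hotforge.structure_io import InterfaceSpec, select_interface

        model = fold_hydrogen_charges(assign_parameters(salt_bridge_dimer))
        rec, lig = select_interface(model, InterfaceSpec(frozenset("A"), frozenset("B")))
        contacts = enumerate_contacts(rec, lig, 4.5)
        table = residue_pair_table(contacts)
        assert table.sum_e_total.sum() == pytest.approx(
            sum(c.e_total for c in contacts), abs=1e-9)
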