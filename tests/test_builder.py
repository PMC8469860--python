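"""Gelatin/PVA construction: sequences, masses, topology, packing."""

from collections import Counter

import numpy as np
import pytest

from gelblend.builder import (BlendComposition, GELATIN_SEQUENCE,
                              build_gelatin_model, build_pva_chain,
                              gelatin_fiber_mass, mass_fraction_pva,
                              pack_amorphous_cell)
from gelblend.engine import minimum_image
from gelblend.errors import ConfigurationError
from gelblend.system import concatenate
from gelblend.templates import get_residue_template


class TestGelatinModel:
    def test_sequence_is_the_fifteen_residue_fiber(self):
        assert len(GELATIN_SEQUENCE) == 15
        assert GELATIN_SEQUENCE[0] == "Pro" and GELATIN_SEQUENCE[-1] == "Lys"

    def test_residue_multiset(self):
        # counted independently from the printed fiber sequence
        assert Counter(GELATIN_SEQUENCE) == {
            "Gly": 5, "Pro": 3, "Hyp": 3, "Glu": 1, "Gln": 1,
            "Ala": 1, "Lys": 1}

    def test_three_identical_fibers(self):
        model = build_gelatin_model(rng=0)
        assert model.n_atoms % 3 == 0
        per_fiber = model.n_atoms // 3
        # identical composition: masses repeat fiber-by-fiber
        m = model.masses.reshape(3, per_fiber)
        assert np.allclose(m[0], m[1]) and np.allclose(m[1], m[2])

    def test_model_mass_is_three_fibers(self):
        model = build_gelatin_model(rng=0)
        assert model.total_mass == pytest.approx(3 * gelatin_fiber_mass())

    def test_atom_count_and_mass_deterministic(self):
        a = build_gelatin_model(rng=1)
        b = build_gelatin_model(rng=2)
        assert a.n_atoms == b.n_atoms
        assert a.total_mass == pytest.approx(b.total_mass)

    def test_unknown_residue_is_fatal(self):
        with pytest.raises(ConfigurationError, match="unknown residue"):
            get_residue_template("Xyz")


class TestPVAChain:
    @pytest.mark.parametrize("n_units", [1, 10])
    def test_one_hydroxyl_per_unit(self, n_units):
        from gelblend.observables import donor_acceptor_density
        chain = build_pva_chain(n_units)
        assert donor_acceptor_density(chain).n_hydroxyl == n_units

    def test_linear_backbone_links(self):
        chain = build_pva_chain(10)
        # bonds between carbons: 1 intra-unit C-C per unit + 9 inter-unit
        cc = sum(1 for i, j in chain.bonds
                 if chain.elements[i] == "C" and chain.elements[j] == "C")
        assert cc == 10 + 9

    def test_interior_unit_formula_c2h4o(self):
        one = build_pva_chain(1)
        # united-atom CH2 + CH + O + H = C2H4O
        assert one.total_mass == pytest.approx(44.053, abs=0.01)
        assert Counter(one.elements) == {"C": 2, "O": 1, "H": 1}

    def test_rejects_empty_chain(self):
        with pytest.raises(ValueError):
            build_pva_chain(0)


class TestMassFraction:
    def test_pure_species_limits(self):
        gel = build_gelatin_model(rng=0)
        pva = build_pva_chain(5)
        assert mass_fraction_pva(gel) == 0.0
        assert mass_fraction_pva(pva) == 1.0

    def test_equal_masses_give_half(self, make_system):
        a = make_system([[0, 0, 0]], masses=[10.0], species="gelatin")
        b = make_system([[5, 0, 0]], masses=[10.0], species="pva")
        assert mass_fraction_pva(concatenate([a, b])) == pytest.approx(0.5)


class TestComposition:
    @pytest.mark.parametrize("target", [0.0, 40.0, 62.0, 70.0])
    def test_modelled_compositions_within_tolerance(self, target):
        if target == 0.0:
            comp = BlendComposition(1, 0, target_pva_mass_percent=0.0)
        else:
            comp = BlendComposition.from_target(target)
        assert abs(comp.achieved_pva_mass_percent - target) <= comp.tolerance

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            BlendComposition(-1, 0)


@pytest.fixture(scope="module")
def packed():
    comp = BlendComposition.from_target(40.0)
    return comp, pack_amorphous_cell(comp, seed=11, initial_density=0.5,
                                     max_minimize_iter=150)


class TestPacking:

    def test_zero_pva_cell_contains_only_gelatin(self):
        comp = BlendComposition(1, 0, target_pva_mass_percent=0.0)
        cell = pack_amorphous_cell(comp, seed=3, max_minimize_iter=50)
        assert set(cell.system.species) == {"gelatin"}

    def test_achieved_mass_percent_recorded(self, packed):
        comp, cell = packed
        measured = 100.0 * mass_fraction_pva(cell.system)
        assert measured == pytest.approx(comp.achieved_pva_mass_percent,
                                         abs=1e-9)

    def test_seeded_determinism(self):
        comp = BlendComposition(1, 0, target_pva_mass_percent=0.0)
        a = pack_amorphous_cell(comp, seed=5, max_minimize_iter=30)
        b = pack_amorphous_cell(comp, seed=5, max_minimize_iter=30)
        assert np.array_equal(a.system.positions, b.system.positions)

    def test_chain_integrity_after_packing(self, packed):
        # no broken/teleported chains: every bond below a sanity ceiling
        _, cell = packed
        s = cell.system
        dr = minimum_image(s.positions[s.bonds[:, 0]]
                           - s.positions[s.bonds[:, 1]], s.cell)
        assert np.linalg.norm(dr, axis=1).max() < 3.0

    def test_composition_conserved_by_packing(self, packed):
        comp, cell = packed
        n_pva_atoms = int((cell.system.species == "pva").sum())
        assert n_pva_atoms == comp.n_pva_chains * comp.pva_units_per_chain * 4

    def test_wrapped_coordinates_inside_box(self, packed):
        _, cell = packed
        s = cell.system.copy()
        s.wrap()
        L = s.box_lengths
        assert np.all(s.positions >= 0) and np.all(s.positions < L)
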