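"""Boundary reactions, bounds policy, unit conversion, biomass equations."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsmforge.boundary_biomass import (
    BiomassEquation,
    CompositionEntry,
    CompositionTable,
    add_boundary_reactions,
    apply_bounds_policy,
    attach_biomass,
    build_biomass_equation,
    content_to_mmol_per_gdw,
    load_molar_masses,
    read_composition_table,
)
from gsmforge.model import BoundsPolicy, MetabolicModel, Metabolite, ModelReaction


class TestBoundaryReactions:
    def test_single_nutrient_adds_pair(self):
        model = MetabolicModel()
        out = add_boundary_reactions(model, {"amino_acids": ["C00062"]})
        assert set(out.reactions) == {"TR_C00062", "EX_C00062"}
        assert out.reactions["TR_C00062"].kind == "transport"
        assert out.reactions["EX_C00062"].kind == "exchange"
        assert {m.compartment for m in out.metabolites.values()} == {"c", "e"}
        out.validate()

    def test_duplicate_boundary_is_an_error(self):
        model = add_boundary_reactions(
            MetabolicModel(), {"amino_acids": ["C00062"]})
        with pytest.raises(ValueError, match="C00062"):
            add_boundary_reactions(model, {"minerals": ["C00062"]})

    def test_reproduces_91_transport_91_exchange_shape(self):
        # class sizes of the reconstruction: 20 amino acids, 28 fatty acids,
        # 5 saccharides, 15 vitamins, 10 minerals, 12 cofactors = 90 nutrients
        # plus one configured extra
        sizes = {"amino_acids": 20, "fatty_acids": 28, "saccharides": 5,
                 "vitamins": 15, "minerals": 10, "cofactors": 12}
        classes = {
            cls: [f"C{idx:02d}{i:03d}" for i in range(n)]
            for idx, (cls, n) in enumerate(sizes.items())
        }
        classes["extras"] = ["C99999"]
        out = add_boundary_reactions(MetabolicModel(), classes)
        kinds = [r.kind for r in out.reactions.values()]
        assert kinds.count("transport") == 91
        assert kinds.count("exchange") == 91


class TestBoundsPolicy:
    def build(self):
        model = MetabolicModel()
        for cid in ("A", "B"):
            model.add_metabolite(Metabolite(compound_id=cid, compartment="c"))
        model.add_reaction(ModelReaction(
            id="R_rev", stoichiometry={"A_c": -1, "B_c": 1}))
        model.add_reaction(ModelReaction(
            id="R_fwd", stoichiometry={"A_c": -1, "B_c": 1}, tags={"forward"}))
        model = add_boundary_reactions(model, {
            "amino_acids": ["F"], "minerals": ["M"], "cofactors": ["W"]})
        return apply_bounds_policy(
            model, BoundsPolicy(), synthesizable={"W"}, trace_elements={"M"})

    def test_kind_and_class_bounds(self):
        model = self.build()
        b = {rid: (r.lower_bound, r.upper_bound) for rid, r in model.reactions.items()}
        assert b["R_rev"] == (-1000.0, 1000.0)
        assert b["R_fwd"] == (0.0, 1000.0)
        assert b["TR_F"] == (-1000.0, 1000.0)
        assert b["EX_F"] == (-5.0, 1000.0)      # feed nutrient
        assert b["EX_M"] == (-1.0, 1000.0)      # trace element
        assert b["EX_W"] == (0.0, 1000.0)       # synthesizable

    def test_unclassified_exchange_defaults_to_feed_with_warning(self, caplog):
        model = MetabolicModel()
        model.add_metabolite(Metabolite(compound_id="Q", compartment="e"))
        model.add_reaction(ModelReaction(
            id="EX_Q", stoichiometry={"Q_e": -1.0}, kind="exchange"))
        with caplog.at_level(logging.WARNING):
            out = apply_bounds_policy(model)
        assert (out.reactions["EX_Q"].lower_bound,
                out.reactions["EX_Q"].upper_bound) == (-5.0, 1000.0)
        assert any("no nutrient class" in r.message for r in caplog.records)

    def test_reconstruction_bounds_invariant(self, staged):
        allowed = {(0.0, 1000.0), (-5.0, 1000.0), (-1.0, 1000.0)}
        for rxn in staged.model.reactions.values():
            if rxn.kind == "exchange":
                assert (rxn.lower_bound, rxn.upper_bound) in allowed
            elif rxn.kind == "transport":
                assert (rxn.lower_bound, rxn.upper_bound) == (-1000.0, 1000.0)


class TestUnitConversion:
    @pytest.mark.parametrize("content,unit,mass,expected", [
        (0.0, "g/100g", 100.0, 0.0),
        (0.0, "mg/kg", 100.0, 0.0),
        (1.0, "g/100g", 100.0, 0.1),
        (1.0, "percent", 100.0, 0.1),
        (1000.0, "mg/kg", 100.0, 0.01),
    ])
    def test_algebra(self, content, unit, mass, expected):
        assert content_to_mmol_per_gdw(content, unit, mass) == pytest.approx(expected)

    def test_dry_basis_divides_by_dry_fraction(self):
        wet = content_to_mmol_per_gdw(2.0, "g/100g", 50.0)
        dry = content_to_mmol_per_gdw(2.0, "g/100g", 50.0,
                                      moisture_fraction=0.75, dry_basis=True)
        assert dry == pytest.approx(wet / 0.25)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(content=st.floats(0.001, 100), mass=st.floats(1, 1000),
           k=st.floats(0.1, 10))
    def test_linear_in_content_inverse_in_mass(self, content, mass, k):
        base = content_to_mmol_per_gdw(content, "g/100g", mass)
        assert content_to_mmol_per_gdw(k * content, "g/100g", mass) == \
            pytest.approx(k * base)
        assert content_to_mmol_per_gdw(content, "g/100g", k * mass) == \
            pytest.approx(base / k)

    def test_errors(self):
        with pytest.raises(ValueError, match="negative"):
            content_to_mmol_per_gdw(-1.0, "g/100g", 10.0)
        with pytest.raises(ValueError, match="unit"):
            content_to_mmol_per_gdw(1.0, "oz/gallon", 10.0)
        with pytest.raises(ValueError, match="molar mass"):
            content_to_mmol_per_gdw(1.0, "g/100g", 0.0)


class TestBiomassEquation:
    def table(self, moisture=0.75):
        return CompositionTable(variety="toy", entries=[
            CompositionEntry("A", 2.0, "g/100g"),
            CompositionEntry("B", 500.0, "mg/kg"),
        ], moisture_fraction=moisture)

    def test_hand_arithmetic(self):
        eq = build_biomass_equation(self.table(), {"A": 50.0, "B": 100.0})
        # (2.0 * 10 / 50) / 0.25 and (500 / 100 / 1000) / 0.25
        assert eq.precursor_coefficients["A"] == pytest.approx(1.6)
        assert eq.precursor_coefficients["B"] == pytest.approx(0.02)
        assert eq.maintenance_coefficient == 29.8303

    def test_moisture_rescales_uniformly(self):
        dry25 = build_biomass_equation(self.table(0.75), {"A": 50.0, "B": 100.0})
        dry50 = build_biomass_equation(self.table(0.50), {"A": 50.0, "B": 100.0})
        ratios = {
            cid: dry25.precursor_coefficients[cid] / dry50.precursor_coefficients[cid]
            for cid in dry25.precursor_coefficients
        }
        assert all(r == pytest.approx(2.0) for r in ratios.values())

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_biomass_equation(
                CompositionTable(variety="toy"), {"A": 50.0})

    def test_missing_molar_mass_lists_compounds(self):
        with pytest.raises(ValueError, match="B"):
            build_biomass_equation(self.table(), {"A": 50.0})

    def test_non_positive_coefficients_rejected(self):
        with pytest.raises(ValueError):
            BiomassEquation(variety="toy", precursor_coefficients={"A": -1.0})

    def test_attach_creates_objective_and_drain(self):
        model = add_boundary_reactions(MetabolicModel(), {"feed": ["A", "B"]})
        model = apply_bounds_policy(model)
        eq = build_biomass_equation(self.table(), {"A": 50.0, "B": 100.0})
        out = attach_biomass(model, eq)
        out.validate()
        assert out.objective == "BIOMASS_toy"
        biomass = out.reactions["BIOMASS_toy"]
        assert biomass.kind == "biomass"
        assert biomass.stoichiometry["A_c"] == pytest.approx(-1.6)
        assert biomass.stoichiometry["C00002_c"] == pytest.approx(-29.8303)
        assert biomass.stoichiometry["C00008_c"] == pytest.approx(29.8303)
        assert out.reactions["EX_BIOMASS"].kind == "exchange"

    def test_nadph_switch(self):
        eq = build_biomass_equation(self.table(), {"A": 50.0, "B": 100.0},
                                    include_nadph=True)
        model = add_boundary_reactions(MetabolicModel(), {"feed": ["A", "B"]})
        out = attach_biomass(model, eq)
        stoich = out.reactions["BIOMASS_toy"].stoichiometry
        assert stoich["C00005_c"] == pytest.approx(-29.8303)  # NADPH consumed
        assert stoich["C00006_c"] == pytest.approx(29.8303)   # NADP+ released
        # and the default equation omits the redox couple entirely
        default = attach_biomass(model, build_biomass_equation(
            self.table(), {"A": 50.0, "B": 100.0}))
        assert "C00005_c" not in default.reactions["BIOMASS_toy"].stoichiometry


class TestCompositionIO:
    def test_reads_variety_and_moisture(self, world):
        d, _ = world
        table = read_composition_table(d / "compositions.tsv", "Riyekuai")
        assert table.variety == "Riyekuai"
        assert 0.5 < table.moisture_fraction < 0.9
        assert all(e.content >= 0 for e in table.entries)
        assert all(e.unit in ("g/100g", "mg/kg") for e in table.entries)

    def test_package_molar_masses(self):
        masses = load_molar_masses()
        assert masses["arginine"] == pytest.approx(174.20)
        assert masses["C00305"] == pytest.approx(24.305)
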