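"""Flat-file parsing and model serialization."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsmforge.model import GPR, MetabolicModel, Metabolite, ModelReaction
from gsmforge.universe_io import (
    UniverseValidationError,
    model_from_dict,
    model_to_dict,
    parse_annotations,
    parse_equation,
    parse_formula,
    parse_universe,
    read_model,
    universe_to_dict,
    write_model,
)

COMPOUNDS_TSV = """id\tname\tformula\tcharge\taliases
C00031\tD-glucose\tC6H12O6\t0\tC00267;C00221
C00267\talpha-D-glucose\tC6H12O6\t0\t
C00001\twater\tH2O\t0\t
C00002\tATP\tC10H16N5O13P3\t-4\t
C00080\tproton\tH\t1\t
C05359\telectron\t-\t-1\t
CGEN\ta sugar\t\t0\t
"""

REACTIONS_TSV = """id\tequation\tdirection\tec_numbers\tmain_reaction_id\tpathways\tsubsystem
R00001\tC00031 <=> C00267\t\t5.1.3.3\t\tpw1\tCarbohydrate
R00002\t2 C00001 => C00031 + C00002\tforward\t1.1.1.1;2.7.1.1\tR00001\tpw1;pw2\t
R00003\tn C00031 => n C00267\t\t\t\t\t
R00004\tC00031 => \t\t\t\t\t
R00005\tCGEN + C00001 <=> C00267\t\t3.2.1.1\t\tpw2\t
"""

PATHWAYS_TSV = "pathway_id\tsubsystem\npw1\tCarbohydrate\npw2\tEnergy\n"
ENZYMES_TSV = "ec\treaction_id\n5.1.3.3\tR00001\n1.1.1.1\tR00002\n"


@pytest.fixture
def tiny_dir(tmp_path):
    (tmp_path / "compounds.tsv").write_text(COMPOUNDS_TSV)
    (tmp_path / "reactions.tsv").write_text(REACTIONS_TSV)
    (tmp_path / "pathways.tsv").write_text(PATHWAYS_TSV)
    (tmp_path / "enzymes.tsv").write_text(ENZYMES_TSV)
    return tmp_path


def parse_tiny(d, generic=frozenset({"CGEN"})):
    return parse_universe(
        d / "compounds.tsv", d / "reactions.tsv", d / "pathways.tsv",
        d / "enzymes.tsv", generic_compounds=set(generic))


class TestParseUniverse:
    def test_compound_fields(self, tiny_dir):
        uni = parse_tiny(tiny_dir)
        glc = uni.compounds["C00031"]
        assert glc.name == "D-glucose"
        assert glc.formula == {"C": 6, "H": 12, "O": 6}
        assert glc.aliases == {"C00267", "C00221"}
        assert uni.compounds["C05359"].formula == {}  # known-empty (electron)
        assert uni.compounds["C05359"].charge == -1
        assert uni.compounds["CGEN"].formula is None  # unknown

    def test_hand_parsed_stoichiometry(self, tiny_dir):
        uni = parse_tiny(tiny_dir)
        assert uni.reactions["R00001"].stoichiometry == {
            "C00031": Fraction(-1), "C00267": Fraction(1)}
        assert uni.reactions["R00001"].direction == "reversible"
        r2 = uni.reactions["R00002"]
        assert r2.stoichiometry == {
            "C00001": Fraction(-2), "C00031": Fraction(1), "C00002": Fraction(1)}
        assert r2.direction == "forward"
        assert r2.ec_numbers == {"1.1.1.1", "2.7.1.1"}
        assert r2.main_reaction_id == "R00001"
        assert r2.pathways == {"pw1", "pw2"}

    def test_flags(self, tiny_dir):
        uni = parse_tiny(tiny_dir)
        assert uni.reactions["R00003"].flags.symbolic_coefficient
        assert uni.reactions["R00004"].flags.incomplete
        assert uni.reactions["R00005"].flags.generic
        assert not uni.reactions["R00001"].flags.generic

    def test_links(self, tiny_dir):
        uni = parse_tiny(tiny_dir)
        assert uni.ec_to_reactions["5.1.3.3"] == {"R00001"}
        assert uni.ec_to_reactions["3.2.1.1"] == {"R00005"}  # from reaction table
        assert uni.pathway_to_subsystem == {"pw1": "Carbohydrate", "pw2": "Energy"}

    def test_empty_files_give_empty_universe(self, tmp_path):
        for name, header in [
            ("compounds.tsv", "id\tname\tformula\tcharge\taliases"),
            ("reactions.tsv", "id\tequation\tdirection\tec_numbers\t"
             "main_reaction_id\tpathways\tsubsystem"),
            ("pathways.tsv", "pathway_id\tsubsystem"),
            ("enzymes.tsv", "ec\treaction_id"),
        ]:
            (tmp_path / name).write_text(header + "\n")
        uni = parse_tiny(tmp_path, generic=frozenset())
        assert uni.compounds == {} and uni.reactions == {}

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="compounds.tsv"):
            parse_tiny(tmp_path)

    def test_unknown_compound_reference_is_validation_error(self, tiny_dir):
        with open(tiny_dir / "reactions.tsv", "a") as fh:
            fh.write("R00099\tCXXXX => C00031\t\t\t\t\t\n")
        with pytest.raises(UniverseValidationError, match="CXXXX"):
            parse_tiny(tiny_dir)

    def test_parsing_is_idempotent(self, tiny_dir):
        a = universe_to_dict(parse_tiny(tiny_dir))
        b = universe_to_dict(parse_tiny(tiny_dir))
        assert a == b


class TestEquationParsing:
    def test_sides_merge_to_net_coefficients(self):
        stoich, direction, symbolic, incomplete = parse_equation(
            "2 C1 + C2 <=> C3 + C1")
        assert stoich == {"C1": Fraction(-1), "C2": Fraction(-1), "C3": Fraction(1)}
        assert direction == "reversible" and not symbolic and not incomplete

    def test_full_cancellation_is_incomplete(self):
        stoich, _, _, incomplete = parse_equation("C1 <=> C1")
        assert stoich == {} and incomplete

    def test_rational_coefficient(self):
        stoich, *_ = parse_equation("1/2 C1 => C2")
        assert stoich["C1"] == Fraction(-1, 2)

    def test_missing_arrow_raises(self):
        with pytest.raises(ValueError, match="arrow"):
            parse_equation("C1 + C2")


class TestParseAnnotations:
    def test_grouping_and_duplicates(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(
            "gene_id\tec\n"
            "g1\t1.1.1.1\ng1\t2.7.1.1\ng1\t1.1.1.1\n"
            "pvm:113803399\t2.7.10.2\n"
            "bad\tnot-an-ec\n"
        )
        anns = parse_annotations(path)
        by_gene = {a.gene_id: a.ec_numbers for a in anns}
        assert by_gene["g1"] == {"1.1.1.1", "2.7.1.1"}
        assert by_gene["pvm:113803399"] == {"2.7.10.2"}  # id taken verbatim
        assert "bad" not in by_gene  # malformed EC skipped with a warning

    def test_shared_ec_indexes_all_genes(self, tmp_path):
        path = tmp_path / "genes.tsv"
        rows = [f"g{i}\t1.1.1.{i}" for i in range(7)]
        rows += [f"h{i}\t9.9.9.9" for i in range(3)]
        path.write_text("gene_id\tec\n" + "\n".join(rows) + "\n")
        anns = parse_annotations(path)
        sharing = {a.gene_id for a in anns if "9.9.9.9" in a.ec_numbers}
        assert sharing == {"h0", "h1", "h2"}


# ---------------------------------------------------------------------------
# Model round-trips
# ---------------------------------------------------------------------------

ids = st.text(alphabet="ABC123", min_size=1, max_size=6)
floats = st.floats(min_value=-50, max_value=50, allow_nan=False).filter(lambda x: x != 0)


@st.composite
def models(draw):
    model = MetabolicModel(id=draw(ids))
    n_met = draw(st.integers(1, 6))
    mets = []
    for i in range(n_met):
        met = Metabolite(
            compound_id=f"C{i}", compartment=draw(st.sampled_from("ce")),
            name=draw(ids), charge=draw(st.integers(-2, 2)),
            formula=draw(st.none() | st.dictionaries(
                st.sampled_from(["C", "H", "O"]), st.integers(1, 9), max_size=3)),
        )
        if met.key not in model.metabolites:
            model.add_metabolite(met)
            mets.append(met.key)
    for j in range(draw(st.integers(0, 5))):
        keys = draw(st.lists(st.sampled_from(mets), min_size=1, max_size=4,
                             unique=True))
        lb = draw(st.floats(-1000, 0))
        gpr = draw(st.none() | st.just(GPR(("or", ("g1", ("and", ("g2", "g3")))))))
        model.add_reaction(ModelReaction(
            id=f"R{j}", stoichiometry={k: draw(floats) for k in keys},
            lower_bound=lb, upper_bound=draw(st.floats(0, 1000)),
            kind=draw(st.sampled_from(["metabolic", "transport", "exchange", "biomass"])),
            gpr=gpr, pathways=set(draw(st.lists(ids, max_size=2))),
            subsystem=draw(st.none() | ids), tags=set(draw(st.lists(ids, max_size=2))),
        ))
    if model.reactions:
        model.objective = sorted(model.reactions)[0]
    return model


class TestModelIO:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(models())
    def test_json_roundtrip_is_lossless(self, model):
        assert model_to_dict(model_from_dict(model_to_dict(model))) == model_to_dict(model)

    def test_empty_model_roundtrip(self, tmp_path):
        path = tmp_path / "empty.json"
        write_model(MetabolicModel(id="empty"), path)
        again = read_model(path)
        assert again.id == "empty" and not again.reactions and not again.metabolites

    def test_json_file_roundtrip_of_reconstructed_model(self, staged, tmp_path):
        path = tmp_path / "model.json"
        write_model(staged.model, path)
        assert model_to_dict(read_model(path)) == model_to_dict(staged.model)

    def test_unknown_format_is_fatal(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_model(MetabolicModel(), tmp_path / "m.json", format="hdf5")

    def test_sbml_roundtrip(self, variety_model, tmp_path):
        path = tmp_path / "model.xml"
        write_model(variety_model, path, format="sbml")
        again = read_model(path)
        assert set(again.reactions) == set(variety_model.reactions)
        assert set(again.metabolites) == set(variety_model.metabolites)
        assert again.objective == variety_model.objective
        for rid, rxn in variety_model.reactions.items():
            back = again.reactions[rid]
            assert back.kind == rxn.kind
            assert back.gpr == rxn.gpr
            assert (back.lower_bound, back.upper_bound) == (
                rxn.lower_bound, rxn.upper_bound)
            for key, coeff in rxn.stoichiometry.items():
                assert back.stoichiometry[key] == pytest.approx(coeff, rel=1e-12)

    def test_sbml_read_by_independent_reader(self, variety_model, tmp_path):
        cobra = pytest.importorskip("cobra")
        path = tmp_path / "model.xml"
        write_model(variety_model, path, format="sbml")
        cm = cobra.io.read_sbml_model(str(path))
        assert len(cm.reactions) == len(variety_model.reactions)
        assert len(cm.metabolites) == len(variety_model.metabolites)
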