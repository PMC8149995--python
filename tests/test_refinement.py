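"""Balancing, chirality, redundancy removal and metadata supplementation."""

from fractions import Fraction

import pytest

from conftest import make_network, make_universe
from gsmforge.refinement import (
    balance_network,
    balance_reaction,
    check_balance,
    remove_redundant,
    resolve_alias_policy,
    standardize_chirality,
    supplement_metadata,
)
from gsmforge.universe_io import Compound, ReactionFlags, ReactionRecord

F = Fraction

WATER, PROTON, ELECTRON = "C00001", "C00080", "C05359"

FILLER_COMPOUNDS = [
    Compound(id=WATER, formula={"H": 2, "O": 1}),
    Compound(id=PROTON, formula={"H": 1}, charge=1),
    Compound(id=ELECTRON, formula={}, charge=-1),
    Compound(id="C01438", formula={"C": 1, "H": 4}),
    Compound(id="C06547", formula={"C": 2, "H": 4}),
]


def cmap(*extra):
    return {c.id: c for c in [*FILLER_COMPOUNDS, *extra]}


class TestCheckBalance:
    def test_isomerization_is_balanced(self):
        comps = cmap(Compound(id="A", formula={"C": 6, "H": 12, "O": 6}),
                     Compound(id="B", formula={"C": 6, "H": 12, "O": 6}))
        rxn = ReactionRecord(id="R", stoichiometry={"A": F(-1), "B": F(1)})
        assert check_balance(rxn, comps).balanced

    def test_hand_counted_deficit(self):
        # glucose -> glucose minus one water: products short H2 and O
        comps = cmap(Compound(id="A", formula={"C": 6, "H": 12, "O": 6}),
                     Compound(id="B", formula={"C": 6, "H": 10, "O": 5}))
        report = check_balance(
            ReactionRecord(id="R", stoichiometry={"A": F(-1), "B": F(1)}), comps)
        assert report.element_deficit == {"H": F(-2), "O": F(-1)}
        assert report.charge_deficit == 0

    def test_electron_is_charge_only(self):
        comps = cmap(Compound(id="A", formula={"C": 1}, charge=1),
                     Compound(id="B", formula={"C": 1}))
        report = check_balance(
            ReactionRecord(id="R", stoichiometry={"A": F(-1), "B": F(1),
                                                  ELECTRON: F(-1)}), comps)
        assert report.balanced  # A+ + e- -> B

    def test_missing_formula_marks_uncomputable(self):
        comps = cmap(Compound(id="A", formula=None),
                     Compound(id="B", formula={"C": 1}))
        report = check_balance(
            ReactionRecord(id="R", stoichiometry={"A": F(-1), "B": F(1)}), comps)
        assert not report.computable and not report.balanced


class TestBalanceReaction:
    def test_already_balanced_unchanged(self):
        comps = cmap(Compound(id="A", formula={"C": 2}),
                     Compound(id="B", formula={"C": 2}))
        rxn = ReactionRecord(id="R", stoichiometry={"A": F(-1), "B": F(1)})
        out, fix = balance_reaction(rxn, comps)
        assert fix == {} and out.stoichiometry == rxn.stoichiometry

    def test_missing_water_fixed_minimally(self):
        comps = cmap(Compound(id="A", formula={"C": 6, "H": 12, "O": 6}),
                     Compound(id="B", formula={"C": 6, "H": 10, "O": 5}))
        rxn = ReactionRecord(id="R", stoichiometry={"A": F(-1), "B": F(1)})
        out, fix = balance_reaction(rxn, comps)
        assert fix == {WATER: F(1)}
        assert out.stoichiometry[WATER] == F(1)
        assert check_balance(out, comps).balanced

    def test_proton_electron_algebra(self):
        # products short two H and one positive charge: 2 H+ + e- on the right
        comps = cmap(Compound(id="A", formula={"C": 1, "H": 4}),
                     Compound(id="B", formula={"C": 1, "H": 2}, charge=-1))
        rxn = ReactionRecord(id="R", stoichiometry={"A": F(-1), "B": F(1)})
        out, fix = balance_reaction(rxn, comps)
        assert fix == {PROTON: F(2), ELECTRON: F(1)}
        assert check_balance(out, comps).balanced

    def test_unbalanceable_flagged_and_unmodified(self):
        comps = cmap(Compound(id="A", formula={"N": 3}),
                     Compound(id="B", formula={"N": 1}))
        rxn = ReactionRecord(id="R", stoichiometry={"A": F(-1), "B": F(1)})
        out, fix = balance_reaction(rxn, comps)
        assert fix is None
        assert out.flags.unbalanceable
        assert out.stoichiometry == rxn.stoichiometry

    def test_planted_fixes_recovered_exactly(self, staged, ground_truth):
        fixes = {rid: {c: int(v) for c, v in fix.items()}
                 for rid, fix in staged.ref_report.balance_fixes.items()}
        assert fixes == ground_truth.unbalanced_fixes

    def test_every_retained_reaction_balanced(self, staged):
        for rid, entry in staged.refined.reactions.items():
            rec = entry.record
            if rec.flags.incomplete or rec.flags.unbalanceable:
                continue
            assert check_balance(rec, staged.universe.compounds).balanced, rid


class TestChirality:
    def records(self):
        return [
            ReactionRecord(id="R1", stoichiometry={"C00031": F(-1), "X": F(1)}),
            ReactionRecord(id="R2", stoichiometry={"C00267": F(-1), "X": F(1)}),
            ReactionRecord(id="R3", stoichiometry={"Y": F(-1), "Z": F(1)}),
        ]

    def test_replacement_and_duplicate_flag(self):
        net = make_network(self.records())
        out, modified = standardize_chirality(net, {"C00031": "C00267"})
        assert modified == ["R1"]
        assert out.reactions["R1"].record.stoichiometry == {
            "C00267": F(-1), "X": F(1)}
        flagged = [rid for rid, e in out.reactions.items()
                   if e.record.flags.chiral_duplicate]
        assert flagged == ["R2"]  # identical to rewritten R1; smaller id kept

    def test_no_aliases_is_noop(self):
        net = make_network(self.records())
        out, modified = standardize_chirality(net, {"C99999": "C00267"})
        assert modified == []
        assert {r.record.stoichiometry == n.record.stoichiometry
                for (_, r), (_, n) in zip(sorted(out.reactions.items()),
                                          sorted(net.reactions.items()))} == {True}

    def test_idempotent(self):
        net = make_network(self.records())
        once, _ = standardize_chirality(net, {"C00031": "C00267"})
        twice, modified = standardize_chirality(once, {"C00031": "C00267"})
        assert modified == []

    def test_self_identical_flagged(self):
        net = make_network([ReactionRecord(
            id="R1", stoichiometry={"C00031": F(-1), "C00267": F(1)})])
        out, _ = standardize_chirality(net, {"C00031": "C00267"})
        assert out.reactions["R1"].record.flags.chiral_duplicate

    def test_alias_cycle_is_fatal(self):
        with pytest.raises(ValueError, match="cycle"):
            resolve_alias_policy({"A": "B", "B": "A"})

    def test_chain_resolution(self):
        assert resolve_alias_policy({"A": "B", "B": "C"}) == {"A": "C", "B": "C"}


class TestRemoveRedundant:
    def test_step_pair_removed_total_kept(self):
        net = make_network([
            ReactionRecord(id="R_ab", stoichiometry={"A": F(-1), "B": F(1)}),
            ReactionRecord(id="R_bc", stoichiometry={"B": F(-1), "C": F(1)}),
            ReactionRecord(id="R_ac", stoichiometry={"A": F(-1), "C": F(1)}),
        ])
        out, report = remove_redundant(net)
        assert sorted(report.removed["step"]) == ["R_ab", "R_bc"]
        assert "R_ac" in out.reactions

    def test_branched_intermediate_kept(self):
        net = make_network([
            ReactionRecord(id="R_ab", stoichiometry={"A": F(-1), "B": F(1)}),
            ReactionRecord(id="R_bc", stoichiometry={"B": F(-1), "C": F(1)}),
            ReactionRecord(id="R_bd", stoichiometry={"B": F(-1), "D": F(1)}),
            ReactionRecord(id="R_ac", stoichiometry={"A": F(-1), "C": F(1)}),
        ])
        out, report = remove_redundant(net)
        assert report.removed["step"] == []
        assert len(out.reactions) == 4

    def test_symbolic_and_incomplete_removed(self):
        net = make_network([
            ReactionRecord(id="R_n", stoichiometry={"A": F(-1), "B": F(1)},
                           flags=ReactionFlags(symbolic_coefficient=True)),
            ReactionRecord(id="R_i", stoichiometry={},
                           flags=ReactionFlags(incomplete=True)),
            ReactionRecord(id="R_g", stoichiometry={"A": F(-1), "G": F(1)},
                           flags=ReactionFlags(generic=True)),
        ])
        out, report = remove_redundant(net)
        assert sorted(report.removed["incomplete_or_symbolic"]) == ["R_i", "R_n"]
        assert report.removed["generic"] == ["R_g"]
        assert out.reactions == {}

    def test_categories_disjoint_and_planted(self, staged, ground_truth):
        removed = staged.ref_report.removed
        all_ids = [rid for ids in removed.values() for rid in ids]
        assert len(all_ids) == len(set(all_ids))
        assert {k: sorted(v) for k, v in removed.items()} == \
               {k: sorted(v) for k, v in ground_truth.removable.items()}


class TestSupplement:
    def universe(self):
        compounds = [Compound(id=c, formula={"C": 1}) for c in ("A", "B", "C")]
        reactions = [
            ReactionRecord(id="R1", stoichiometry={"A": F(-1), "B": F(1)},
                           pathways={"pw1"}, main_reaction_id="R9"),
            ReactionRecord(id="R2", stoichiometry={"A": F(-1), "C": F(1)},
                           pathways={"pw1"}),
        ]
        return make_universe(compounds, reactions, {"pw1": "Carbs"})

    def test_subsystem_from_pathway_link(self):
        uni = self.universe()
        net = make_network([uni.reactions["R1"].copy()])
        out, report = supplement_metadata(net, uni)
        assert out.reactions["R1"].record.subsystem == "Carbs"
        assert report.metadata_supplemented_count == 1

    def test_pathway_from_metabolite_intersection(self):
        uni = self.universe()
        rec = ReactionRecord(id="R3", stoichiometry={"A": F(-1), "B": F(1)})
        net = make_network([rec])
        out, _ = supplement_metadata(net, uni)
        # both metabolites occur only in pw1 reactions
        assert out.reactions["R3"].record.pathways == {"pw1"}

    def test_uninferable_fields_stay_empty(self):
        uni = self.universe()
        rec = ReactionRecord(id="R4", stoichiometry={"Q": F(-1), "Z": F(1)})
        net = make_network([rec])
        out, report = supplement_metadata(net, uni)
        assert out.reactions["R4"].record.pathways == set()
        assert out.reactions["R4"].record.subsystem is None
        assert report.metadata_supplemented_count == 0
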