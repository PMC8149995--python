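"""Draft gene-enzyme-reaction network assembly.

EC numbers bridge the genome annotation to the reference reactions: a
reaction enters the draft iff at least one of its EC numbers carries at
least one annotated gene.  Genes encoding the same enzyme (same EC of the
reaction) are combined with AND (treated as subunits of a complex); genes
reached through different ECs are alternatives and combine with OR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from gsmforge.model import GPR
from gsmforge.universe_io import GeneAnnotation, ReactionRecord, Universe

log = logging.getLogger(__name__)


@dataclass
class DraftEntry:
    record: ReactionRecord
    gpr: GPR | None
    genes: frozenset[str]
    enzymes: frozenset[str]


@dataclass
class DraftNetwork:
    reactions: dict[str, DraftEntry] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for entry in self.reactions.values():
            out |= entry.genes
        return out

    @property
    def enzymes(self) -> set[str]:
        out: set[str] = set()
        for entry in self.reactions.values():
            out |= entry.enzymes
        return out

    @property
    def pathways(self) -> set[str]:
        out: set[str] = set()
        for entry in self.reactions.values():
            out |= entry.record.pathways
        return out

    @property
    def subsystems(self) -> set[str]:
        return {
            e.record.subsystem for e in self.reactions.values()
            if e.record.subsystem is not None
        }

    @property
    def metabolites(self) -> set[str]:
        out: set[str] = set()
        for entry in self.reactions.values():
            out |= set(entry.record.stoichiometry)
        return out

    def summary(self) -> dict[str, int]:
        return {
            "genes": len(self.genes),
            "enzymes": len(self.enzymes),
            "reactions": len(self.reactions),
            "pathways": len(self.pathways),
            "subsystems": len(self.subsystems),
        }

    def copy(self) -> "DraftNetwork":
        return DraftNetwork(reactions={
            rid: DraftEntry(
                record=e.record.copy(), gpr=e.gpr,
                genes=e.genes, enzymes=e.enzymes,
            )
            for rid, e in self.reactions.items()
        })


def draft_to_dict(network: DraftNetwork) -> dict:
    from gsmforge.universe_io import _record_to_dict

    return {
        "reactions": [
            {
                "record": _record_to_dict(e.record),
                "gpr": e.gpr.to_json() if e.gpr is not None else None,
                "genes": sorted(e.genes),
                "enzymes": sorted(e.enzymes),
            }
            for _, e in sorted(network.reactions.items())
        ]
    }


def draft_from_dict(data: dict) -> DraftNetwork:
    from gsmforge.universe_io import _record_from_dict

    network = DraftNetwork()
    for item in data["reactions"]:
        record = _record_from_dict(item["record"])
        network.reactions[record.id] = DraftEntry(
            record=record,
            gpr=GPR.from_json(item["gpr"]) if item["gpr"] is not None else None,
            genes=frozenset(item["genes"]),
            enzymes=frozenset(item["enzymes"]),
        )
    return network


def map_genes_to_reactions(
    universe: Universe, annotations: Iterable[GeneAnnotation]
) -> dict[str, set[tuple[str, str]]]:
    """Join annotations to reactions over shared EC numbers.

    Returns reaction id -> set of (gene, EC) pairs, where the EC records
    which enzyme justified attaching the gene.
    """
    ec_to_genes: dict[str, set[str]] = {}
    for ann in annotations:
        for ec in ann.ec_numbers:
            ec_to_genes.setdefault(ec, set()).add(ann.gene_id)

    mapping: dict[str, set[tuple[str, str]]] = {}
    for ec, rids in universe.ec_to_reactions.items():
        genes = ec_to_genes.get(ec)
        if not genes:
            continue
        for rid in rids:
            pairs = mapping.setdefault(rid, set())
            pairs.update((g, ec) for g in genes)
    return mapping


def build_gpr(pairs: Iterable[tuple[str, str]]) -> GPR:
    """Build the boolean rule for one reaction from its (gene, EC) pairs.

    Same-EC genes -> AND (complex subunits); distinct ECs -> OR.
    """
    pairs = set(pairs)
    if not pairs:
        raise ValueError("cannot build a GPR from an empty pair set")
    by_ec: dict[str, set[str]] = {}
    for gene, ec in pairs:
        by_ec.setdefault(ec, set()).add(gene)
    alternatives = []
    for ec in sorted(by_ec):
        genes = sorted(by_ec[ec])
        alternatives.append(genes[0] if len(genes) == 1 else ("and", tuple(genes)))
    if len(alternatives) == 1:
        return GPR(alternatives[0])
    return GPR(("or", tuple(alternatives)))


def assemble_draft(
    universe: Universe, annotations: Iterable[GeneAnnotation]
) -> DraftNetwork:
    """Assemble the draft network: mapped reactions with GPRs, pathway and
    subsystem metadata propagated from the universe."""
    annotations = set(annotations)
    mapping = map_genes_to_reactions(universe, annotations)
    draft = DraftNetwork()
    for rid in sorted(mapping):
        pairs = mapping[rid]
        record = universe.reactions[rid].copy()
        draft.reactions[rid] = DraftEntry(
            record=record,
            gpr=build_gpr(pairs),
            genes=frozenset(g for g, _ in pairs),
            enzymes=frozenset(ec for _, ec in pairs),
        )
    if not draft.reactions:
        log.warning("no annotated EC matches any universe reaction: empty draft")
    log.info("draft network: %s", draft.summary())
    return draft
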