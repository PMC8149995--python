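"""Core constraint-based model containers.

A :class:`MetabolicModel` is the compartmentalized, bounded object that the
reconstruction pipeline produces and that FBA consumes: metabolites keyed by
``<compound>_<compartment>``, reactions with stoichiometry, flux bounds in
mmol gDW^-1 h^-1, an optional gene-protein-reaction (GPR) rule, a kind tag
(metabolic / transport / exchange / biomass) and exactly one objective.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

GPRNode = Union[str, tuple]  # leaf gene id, or ("and"|"or", (children...))


def _normalize(node: GPRNode) -> GPRNode:
    """Flatten nested same-operator nodes, drop single-child internal nodes."""
    if isinstance(node, str):
        return node
    op, children = node
    if op not in ("and", "or"):
        raise ValueError(f"unknown GPR operator: {op!r}")
    flat: list[GPRNode] = []
    for child in children:
        child = _normalize(child)
        if isinstance(child, tuple) and child[0] == op:
            flat.extend(child[1])
        else:
            flat.append(child)
    # deduplicate, deterministic order: leaves sorted first, subtrees after
    seen, uniq = set(), []
    for child in flat:
        key = child if isinstance(child, str) else repr(child)
        if key not in seen:
            seen.add(key)
            uniq.append(child)
    uniq.sort(key=lambda c: (isinstance(c, tuple), c if isinstance(c, str) else repr(c)))
    if len(uniq) == 1:
        return uniq[0]
    return (op, tuple(uniq))


@dataclass(frozen=True)
class GPR:
    """Boolean gene-protein-reaction rule.

    ``expression`` is a tree of ``("and", children)`` / ``("or", children)``
    tuples with gene-id strings at the leaves.  Genes encoding subunits of the
    same enzyme combine with AND; genes encoding alternative enzymes combine
    with OR.
    """

    expression: GPRNode

    def __post_init__(self):
        object.__setattr__(self, "expression", _normalize(self.expression))

    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node: GPRNode) -> None:
            if isinstance(node, str):
                out.add(node)
            else:
                for child in node[1]:
                    walk(child)

        walk(self.expression)
        return frozenset(out)

    def to_string(self) -> str:
        def render(node: GPRNode, parent_op: Optional[str] = None) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            joined = f" {op} ".join(render(c, op) for c in children)
            if parent_op is not None and parent_op != op:
                return f"({joined})"
            return joined

        return render(self.expression)

    def to_json(self):
        def encode(node: GPRNode):
            if isinstance(node, str):
                return node
            return [node[0], *[encode(c) for c in node[1]]]

        return encode(self.expression)

    @classmethod
    def from_json(cls, obj) -> "GPR":
        def decode(node) -> GPRNode:
            if isinstance(node, str):
                return node
            return (node[0], tuple(decode(c) for c in node[1:]))

        return cls(decode(obj))


# ---------------------------------------------------------------------------
# Metabolites and reactions
# ---------------------------------------------------------------------------

COMPARTMENTS = ("c", "e")


def met_key(compound_id: str, compartment: str) -> str:
    return f"{compound_id}_{compartment}"


@dataclass(frozen=True)
class Metabolite:
    """A compound placed in a compartment; the same compound in different
    compartments is a distinct metabolite."""

    compound_id: str
    compartment: str  # "c" cytosol, "e" extracellular
    name: str = ""
    formula: Optional[Mapping[str, int]] = None
    charge: int = 0

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.formula is not None:
            object.__setattr__(self, "formula", dict(self.formula))

    @property
    def key(self) -> str:
        return met_key(self.compound_id, self.compartment)


REACTION_KINDS = ("metabolic", "transport", "exchange", "biomass")


@dataclass
class ModelReaction:
    """A bounded model reaction over compartmentalized metabolites.

    Stoichiometry maps metabolite keys to signed coefficients
    (negative = substrate, positive = product); bounds are fluxes in
    mmol gDW^-1 h^-1.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    kind: str = "metabolic"
    gpr: Optional[GPR] = None
    pathways: set[str] = field(default_factory=set)
    subsystem: Optional[str] = None
    tags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r}")
        self.stoichiometry = {k: float(v) for k, v in self.stoichiometry.items()}
        self.pathways = set(self.pathways)
        self.tags = set(self.tags)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class BoundsPolicy:
    """Flux-bound assignments by reaction class (mmol gDW^-1 h^-1).

    Exchange bounds encode the feeding regime: a negative lower bound is the
    maximal uptake rate.  Nutrients the network can synthesize get no uptake,
    feed nutrients may be taken up at up to 5, trace elements at up to 1.
    """

    reversible: tuple[float, float] = (-1000.0, 1000.0)
    irreversible: tuple[float, float] = (0.0, 1000.0)
    transport: tuple[float, float] = (-1000.0, 1000.0)
    exchange_synthesizable: tuple[float, float] = (0.0, 1000.0)
    exchange_feed_nutrient: tuple[float, float] = (-5.0, 1000.0)
    exchange_trace_element: tuple[float, float] = (-1.0, 1000.0)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


class ModelValidationError(ValueError):
    pass


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, ModelReaction] = field(default_factory=dict)
    objective: Optional[str] = None  # reaction id

    def add_metabolite(self, met: Metabolite, exist_ok: bool = True) -> Metabolite:
        existing = self.metabolites.get(met.key)
        if existing is not None:
            if not exist_ok:
                raise ModelValidationError(f"duplicate metabolite {met.key}")
            return existing
        self.metabolites[met.key] = met
        return met

    def add_reaction(self, rxn: ModelReaction, exist_ok: bool = False) -> None:
        if rxn.id in self.reactions and not exist_ok:
            raise ModelValidationError(f"duplicate reaction id {rxn.id}")
        missing = [k for k in rxn.stoichiometry if k not in self.metabolites]
        if missing:
            raise ModelValidationError(
                f"reaction {rxn.id} references unknown metabolites: {sorted(missing)}"
            )
        self.reactions[rxn.id] = rxn

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- queries ------------------------------------------------------------

    def reactions_of_kind(self, kind: str) -> list[ModelReaction]:
        return [r for rid, r in sorted(self.reactions.items()) if r.kind == kind]

    def exchange_for(self, compound_id: str) -> Optional[ModelReaction]:
        """The exchange reaction whose single species is ``compound_id``."""
        for rid in sorted(self.reactions):
            rxn = self.reactions[rid]
            if rxn.kind != "exchange":
                continue
            cids = {self.metabolites[k].compound_id for k in rxn.stoichiometry}
            if cids == {compound_id}:
                return rxn
        return None

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise ModelValidationError on the
        first violation."""
        for key, met in self.metabolites.items():
            if key != met.key:
                raise ModelValidationError(f"metabolite stored under wrong key {key}")
        for rid, rxn in self.reactions.items():
            if rid != rxn.id:
                raise ModelValidationError(f"reaction stored under wrong id {rid}")
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(f"reaction {rid}: lb > ub")
            missing = [k for k in rxn.stoichiometry if k not in self.metabolites]
            if missing:
                raise ModelValidationError(
                    f"reaction {rid} references unknown metabolites: {sorted(missing)}"
                )
            comps = {self.metabolites[k].compartment for k in rxn.stoichiometry}
            if rxn.kind == "metabolic" and comps - {"c"}:
                raise ModelValidationError(f"metabolic reaction {rid} leaves cytosol")
            if rxn.kind == "transport" and comps != {"c", "e"}:
                raise ModelValidationError(
                    f"transport reaction {rid} must span both compartments"
                )
            if rxn.kind == "exchange":
                if len(rxn.stoichiometry) != 1 or comps != {"e"}:
                    raise ModelValidationError(
                        f"exchange reaction {rid} must have exactly one "
                        "extracellular species"
                    )
        if self.objective is not None and self.objective not in self.reactions:
            raise ModelValidationError(f"objective {self.objective!r} not a reaction")

    def summary(self) -> dict[str, int]:
        kinds = {k: 0 for k in REACTION_KINDS}
        for rxn in self.reactions.values():
            kinds[rxn.kind] += 1
        comps = {"c": 0, "e": 0}
        for met in self.metabolites.values():
            comps[met.compartment] += 1
        genes: set[str] = set()
        for rxn in self.reactions.values():
            if rxn.gpr is not None:
                genes |= rxn.gpr.genes()
        return {
            "reactions": len(self.reactions),
            "metabolites": len(self.metabolites),
            "genes": len(genes),
            "metabolic": kinds["metabolic"],
            "transport": kinds["transport"],
            "exchange": kinds["exchange"],
            "biomass": kinds["biomass"],
            "cytosol_metabolites": comps["c"],
            "extracellular_metabolites": comps["e"],
        }
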