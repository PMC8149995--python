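"""Boundary reactions, bounds policy and biomass equation construction.

The refined network becomes a two-compartment model (cytosol ``c``,
extracellular ``e``).  Each fed or secreted nutrient gets one transport
reaction ``X(e) <-> X(c)`` and one exchange reaction ``X(e) <-> (outside)``;
negative exchange flux is uptake.  Bounds follow the reconstruction's
feeding regime: reversible (-1000, 1000), irreversible (0, 1000), transport
(-1000, 1000); exchanges (0, 1000) for nutrients the network can synthesize,
(-5, 1000) for feed nutrients, (-1, 1000) for trace elements.

Biomass: measured contents (g/100 g, mg/kg or percent) are converted to
mmol per gram dry weight -- gDW is total mass minus water, so dry-basis
coefficients divide by (1 - moisture fraction) -- and used directly as
stoichiometric coefficients of a biomass pseudo-reaction.  Energy
maintenance adds ATP + H2O consumption and ADP + phosphate + H+ production
at a common coefficient (default 29.8303 mmol/gDW, taken from the closest
available animal model).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

from gsmforge.draft_network import DraftNetwork
from gsmforge.model import (
    BoundsPolicy,
    MetabolicModel,
    Metabolite,
    ModelReaction,
    met_key,
)
from gsmforge.universe_io import Universe

log = logging.getLogger(__name__)

ATP, ADP, PHOSPHATE, PROTON, WATER, NADPH, NADP = (
    "C00002", "C00008", "C00009", "C00080", "C00001", "C00005", "C00006",
)

BIOMASS_SPECIES = "BIOMASS"
DEFAULT_MAINTENANCE = 29.8303


# ---------------------------------------------------------------------------
# Network -> model
# ---------------------------------------------------------------------------


def network_to_model(
    network: DraftNetwork,
    universe: Optional[Universe] = None,
    model_id: str = "model",
) -> MetabolicModel:
    """Place every network reaction in the cytosol as a metabolic model
    reaction.  Irreversibility is recorded as a ``forward`` tag; numeric
    bounds are assigned later by :func:`apply_bounds_policy`."""
    model = MetabolicModel(id=model_id)
    compounds = universe.compounds if universe is not None else {}
    for rid in sorted(network.reactions):
        entry = network.reactions[rid]
        record = entry.record
        stoich = {}
        for cid, coeff in record.stoichiometry.items():
            compound = compounds.get(cid)
            model.add_metabolite(Metabolite(
                compound_id=cid,
                compartment="c",
                name=compound.name if compound else "",
                formula=compound.formula if compound else None,
                charge=compound.charge if compound else 0,
            ))
            stoich[met_key(cid, "c")] = float(coeff)
        tags = {"gapfilled"} if entry.gpr is None and not entry.genes else set()
        if record.direction == "forward":
            tags.add("forward")
        model.add_reaction(ModelReaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=0.0 if record.direction == "forward" else -1000.0,
            upper_bound=1000.0,
            kind="metabolic",
            gpr=entry.gpr,
            pathways=set(record.pathways),
            subsystem=record.subsystem,
            tags=tags,
        ))
    return model


# ---------------------------------------------------------------------------
# Boundary reactions
# ---------------------------------------------------------------------------


def transport_id(compound_id: str) -> str:
    return f"TR_{compound_id}"


def exchange_id(compound_id: str) -> str:
    return f"EX_{compound_id}"


def add_boundary_reactions(
    model: MetabolicModel,
    nutrient_classes: Mapping[str, Sequence[str]],
) -> MetabolicModel:
    """Add one transport and one exchange reaction per nutrient.

    ``nutrient_classes`` maps a class name (amino_acids, fatty_acids,
    saccharides, vitamins, minerals, cofactors ...) to compound ids; the
    class name is recorded as a tag on both boundary reactions.  Adding a
    boundary pair twice for the same compound is an error, not silent
    duplication."""
    out = model.copy()
    for cls in sorted(nutrient_classes):
        for cid in nutrient_classes[cls]:
            tid, eid = transport_id(cid), exchange_id(cid)
            if tid in out.reactions or eid in out.reactions:
                raise ValueError(f"boundary reactions already exist for {cid}")
            template = out.metabolites.get(met_key(cid, "c"))
            for comp in ("c", "e"):
                out.add_metabolite(Metabolite(
                    compound_id=cid,
                    compartment=comp,
                    name=template.name if template else "",
                    formula=template.formula if template else None,
                    charge=template.charge if template else 0,
                ))
            out.add_reaction(ModelReaction(
                id=tid,
                stoichiometry={met_key(cid, "e"): -1.0, met_key(cid, "c"): 1.0},
                lower_bound=-1000.0, upper_bound=1000.0,
                kind="transport", tags={cls},
            ))
            out.add_reaction(ModelReaction(
                id=eid,
                stoichiometry={met_key(cid, "e"): -1.0},
                lower_bound=-1000.0, upper_bound=1000.0,
                kind="exchange", tags={cls},
            ))
    return out


def apply_bounds_policy(
    model: MetabolicModel,
    policy: Optional[BoundsPolicy] = None,
    synthesizable: Optional[set[str]] = None,
    trace_elements: Optional[set[str]] = None,
) -> MetabolicModel:
    """Set every reaction's bounds from its kind and classification.

    Exchange classification precedence: trace element > synthesizable >
    feed nutrient; an exchange compound in no declared class defaults to a
    feed nutrient with a warning."""
    policy = policy or BoundsPolicy()
    synthesizable = synthesizable or set()
    trace_elements = trace_elements or set()
    out = model.copy()
    for rid in sorted(out.reactions):
        rxn = out.reactions[rid]
        if rxn.kind == "metabolic":
            lo, hi = policy.irreversible if "forward" in rxn.tags else policy.reversible
        elif rxn.kind == "transport":
            lo, hi = policy.transport
        elif rxn.kind == "exchange":
            cid = out.metabolites[next(iter(rxn.stoichiometry))].compound_id
            if "biomass" in rxn.tags or cid == BIOMASS_SPECIES:
                lo, hi = (0.0, 1000.0)
            elif cid in trace_elements:
                lo, hi = policy.exchange_trace_element
            elif cid in synthesizable:
                lo, hi = policy.exchange_synthesizable
            else:
                if not rxn.tags:
                    log.warning("exchange %s: compound %s in no nutrient class; "
                                "treating as feed nutrient", rid, cid)
                lo, hi = policy.exchange_feed_nutrient
        else:  # biomass reaction flux is the growth rate, never negative
            lo, hi = (0.0, 1000.0)
        rxn.lower_bound, rxn.upper_bound = lo, hi
    return out


# ---------------------------------------------------------------------------
# Unit conversion and composition tables
# ---------------------------------------------------------------------------

UNITS = ("g/100g", "mg/kg", "percent")


def content_to_mmol_per_gdw(
    content: float,
    unit: str,
    molar_mass: float,
    moisture_fraction: float = 0.0,
    dry_basis: bool = False,
) -> float:
    """Convert a measured content to mmol per gram (dry weight if
    *dry_basis*).

    g/100 g (or percent): content * 10 / M; mg/kg: content / M / 1000;
    dry basis divides by (1 - moisture_fraction), i.e. normalizes to the
    water-free mass."""
    if content < 0:
        raise ValueError(f"negative content: {content}")
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass}")
    if not 0 <= moisture_fraction < 1:
        raise ValueError(f"moisture fraction out of [0, 1): {moisture_fraction}")
    if unit in ("g/100g", "percent"):
        value = content * 10.0 / molar_mass
    elif unit == "mg/kg":
        value = content / molar_mass / 1000.0
    else:
        raise ValueError(f"unknown unit {unit!r} (expected one of {UNITS})")
    if dry_basis:
        value /= 1.0 - moisture_fraction
    return value


@dataclass
class CompositionEntry:
    compound_id: str
    content: float
    unit: str


@dataclass
class CompositionTable:
    """Measured nutrient contents for one variety, plus its moisture
    (water mass fraction of the fresh sample)."""

    variety: str
    entries: list[CompositionEntry] = field(default_factory=list)
    moisture_fraction: float = 0.0

    def __post_init__(self):
        if not 0 <= self.moisture_fraction < 1:
            raise ValueError("moisture fraction out of [0, 1)")
        for e in self.entries:
            if e.content < 0:
                raise ValueError(f"negative content for {e.compound_id}")


MOISTURE_ROW = "MOISTURE"


def read_composition_table(path: str | Path, variety: Optional[str] = None) -> CompositionTable:
    """Read a composition TSV (columns: variety, compound_id, content, unit).

    Moisture rides in a sidecar row with compound_id ``MOISTURE`` and unit
    ``fraction``."""
    entries: list[CompositionEntry] = []
    moisture = 0.0
    name = variety
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if variety is not None and row["variety"] != variety:
                continue
            name = name or row["variety"]
            if row["compound_id"] == MOISTURE_ROW:
                moisture = float(row["content"])
                continue
            entries.append(CompositionEntry(
                compound_id=row["compound_id"],
                content=float(row["content"]),
                unit=row["unit"],
            ))
    if name is None:
        raise ValueError(f"no composition rows found in {path}")
    return CompositionTable(variety=name, entries=entries, moisture_fraction=moisture)


def load_molar_masses(path: Optional[str | Path] = None) -> dict[str, float]:
    """Molar masses (g/mol) keyed by compound id and by lower-cased name.

    Defaults to the table shipped as package data (amino acids, fatty acids,
    saccharides, minerals, nucleotides)."""
    out: dict[str, float] = {}
    if path is None:
        source = resources.files("gsmforge").joinpath("data/molar_masses.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        mass = float(row["molar_mass"])
        out[row["compound_id"]] = mass
        if row.get("name"):
            out[row["name"].strip().lower()] = mass
    return out


# ---------------------------------------------------------------------------
# Biomass equation
# ---------------------------------------------------------------------------


@dataclass
class BiomassEquation:
    """Precursor demands in mmol/gDW plus maintenance cofactor terms."""

    variety: str
    precursor_coefficients: dict[str, float]  # compound id -> mmol/gDW consumed
    maintenance_coefficient: float = DEFAULT_MAINTENANCE
    include_nadph: bool = False

    def __post_init__(self):
        bad = {c: v for c, v in self.precursor_coefficients.items() if v <= 0}
        if bad:
            raise ValueError(f"non-positive biomass coefficients: {bad}")


def build_biomass_equation(
    composition: CompositionTable,
    molar_masses: Mapping[str, float],
    maintenance_coefficient: float = DEFAULT_MAINTENANCE,
    include_nadph: bool = False,
) -> BiomassEquation:
    """Convert every measured entry to mmol/gDW (dry basis, using the
    table's moisture) and assemble the biomass equation."""
    if not composition.entries:
        raise ValueError(f"empty composition table for {composition.variety}")
    missing = [e.compound_id for e in composition.entries if e.compound_id not in molar_masses]
    if missing:
        raise ValueError(f"no molar mass for: {sorted(missing)}")
    coeffs: dict[str, float] = {}
    for entry in composition.entries:
        value = content_to_mmol_per_gdw(
            entry.content, entry.unit, molar_masses[entry.compound_id],
            moisture_fraction=composition.moisture_fraction, dry_basis=True,
        )
        if value > 0:
            coeffs[entry.compound_id] = coeffs.get(entry.compound_id, 0.0) + value
    return BiomassEquation(
        variety=composition.variety,
        precursor_coefficients=coeffs,
        maintenance_coefficient=maintenance_coefficient,
        include_nadph=include_nadph,
    )


def biomass_reaction_id(variety: str) -> str:
    return f"BIOMASS_{variety}"


def attach_biomass(model: MetabolicModel, equation: BiomassEquation) -> MetabolicModel:
    """Attach the biomass reaction (kind=biomass) and its drain exchange.

    The reaction consumes the precursors and maintenance ATP + H2O in the
    cytosol, releases ADP + phosphate + H+ (and optionally cycles NADPH) and
    produces one unit of an extracellular biomass pseudo-species drained by
    a standard exchange; the biomass reaction becomes the objective."""
    out = model.copy()
    stoich: dict[str, float] = {}
    for cid, coeff in equation.precursor_coefficients.items():
        out.add_metabolite(Metabolite(compound_id=cid, compartment="c"))
        stoich[met_key(cid, "c")] = stoich.get(met_key(cid, "c"), 0.0) - coeff
    m = equation.maintenance_coefficient
    consumed = [ATP, WATER] + ([NADPH] if equation.include_nadph else [])
    produced = [ADP, PHOSPHATE, PROTON] + ([NADP] if equation.include_nadph else [])
    for cid in consumed:
        out.add_metabolite(Metabolite(compound_id=cid, compartment="c"))
        stoich[met_key(cid, "c")] = stoich.get(met_key(cid, "c"), 0.0) - m
    for cid in produced:
        out.add_metabolite(Metabolite(compound_id=cid, compartment="c"))
        stoich[met_key(cid, "c")] = stoich.get(met_key(cid, "c"), 0.0) + m
    stoich = {k: v for k, v in stoich.items() if v != 0.0}

    out.add_metabolite(Metabolite(compound_id=BIOMASS_SPECIES, compartment="e",
                                  name="biomass pseudo-species"))
    stoich[met_key(BIOMASS_SPECIES, "e")] = 1.0
    rid = biomass_reaction_id(equation.variety)
    out.add_reaction(ModelReaction(
        id=rid, stoichiometry=stoich,
        lower_bound=0.0, upper_bound=1000.0,
        kind="biomass", tags={"biomass"},
    ))
    eid = exchange_id(BIOMASS_SPECIES)
    if eid not in out.reactions:
        out.add_reaction(ModelReaction(
            id=eid,
            stoichiometry={met_key(BIOMASS_SPECIES, "e"): -1.0},
            lower_bound=0.0, upper_bound=1000.0,
            kind="exchange", tags={"biomass"},
        ))
    out.objective = rid
    return out
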