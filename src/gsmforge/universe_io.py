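"""Parsing of KEGG-style flat files and model serialization.

The reference knowledge base (the *universe*) is read from five tab-separated
tables with a fixed, documented column order (KEGG's native multi-line flat
format is assumed to be converted upstream):

``compounds.tsv``
    ``id  name  formula  charge  aliases``; *formula* is a Hill-style string
    ("C6H12O6"), ``-`` means a known-empty formula (e.g. the electron) and an
    empty field means unknown; *aliases* is a ``;``-separated list of
    accession ids that are chiral variants of the same molecule.
``reactions.tsv``
    ``id  equation  direction  ec_numbers  main_reaction_id  pathways
    subsystem``; the equation uses ``<=>`` (reversible) or ``=>`` (forward)
    and ``+``-separated terms with optional integer/rational coefficients.
    The tokens ``m`` and ``n`` are accepted as symbolic coefficients and set
    a flag instead of failing.
``pathways.tsv``
    ``pathway_id  subsystem`` links.
``enzymes.tsv``
    ``ec  reaction_id`` links.
``genes.tsv``
    ``gene_id  ec`` genome annotation (one row per gene/EC pair).

Models round-trip through a versioned JSON schema and export to SBML Level 3
with the fbc package (bounds, objective and gene associations included).
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional

from gsmforge.model import (
    GPR,
    MetabolicModel,
    Metabolite,
    ModelReaction,
)

log = logging.getLogger(__name__)

EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")
FORMULA_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class UniverseValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Compound:
    id: str
    name: str = ""
    formula: Optional[dict[str, int]] = None  # None = unknown composition
    charge: int = 0
    aliases: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.aliases = set(self.aliases) - {self.id}
        if self.formula is not None:
            self.formula = {el: int(n) for el, n in self.formula.items() if int(n) != 0}
            if any(n < 0 for n in self.formula.values()):
                raise UniverseValidationError(f"negative formula count in {self.id}")


@dataclass
class ReactionFlags:
    generic: bool = False
    incomplete: bool = False
    symbolic_coefficient: bool = False
    chiral_duplicate: bool = False
    unbalanceable: bool = False


@dataclass
class ReactionRecord:
    """One reference reaction: net stoichiometry (negative = substrate),
    direction, EC links and pathway metadata."""

    id: str
    stoichiometry: dict[str, Fraction]
    direction: str = "reversible"  # or "forward"
    ec_numbers: set[str] = field(default_factory=set)
    main_reaction_id: Optional[str] = None
    pathways: set[str] = field(default_factory=set)
    subsystem: Optional[str] = None
    flags: ReactionFlags = field(default_factory=ReactionFlags)

    def __post_init__(self):
        if self.direction not in ("reversible", "forward"):
            raise UniverseValidationError(
                f"reaction {self.id}: bad direction {self.direction!r}"
            )
        self.stoichiometry = {
            cid: Fraction(c) for cid, c in self.stoichiometry.items() if Fraction(c) != 0
        }
        self.ec_numbers = set(self.ec_numbers)
        self.pathways = set(self.pathways)
        if not self.stoichiometry and not self.flags.incomplete:
            raise UniverseValidationError(
                f"reaction {self.id}: empty stoichiometry without incomplete flag"
            )

    @property
    def substrates(self) -> set[str]:
        return {c for c, v in self.stoichiometry.items() if v < 0}

    @property
    def products(self) -> set[str]:
        return {c for c, v in self.stoichiometry.items() if v > 0}

    def copy(self) -> "ReactionRecord":
        return ReactionRecord(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            direction=self.direction,
            ec_numbers=set(self.ec_numbers),
            main_reaction_id=self.main_reaction_id,
            pathways=set(self.pathways),
            subsystem=self.subsystem,
            flags=ReactionFlags(**vars(self.flags)),
        )


@dataclass
class Universe:
    """The reference compound/reaction/enzyme/pathway knowledge base."""

    compounds: dict[str, Compound] = field(default_factory=dict)
    reactions: dict[str, ReactionRecord] = field(default_factory=dict)
    ec_to_reactions: dict[str, set[str]] = field(default_factory=dict)
    pathway_to_subsystem: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        offenders = []
        for rid, rxn in self.reactions.items():
            for cid in rxn.stoichiometry:
                if cid not in self.compounds:
                    offenders.append((rid, cid))
        if offenders:
            raise UniverseValidationError(
                f"reactions reference unknown compounds: {offenders[:20]}"
            )
        for ec, rids in self.ec_to_reactions.items():
            for rid in rids:
                if rid not in self.reactions:
                    raise UniverseValidationError(
                        f"EC {ec} links to unknown reaction {rid}"
                    )

    def compound_to_reactions(self) -> dict[str, set[str]]:
        index: dict[str, set[str]] = {}
        for rid, rxn in self.reactions.items():
            for cid in rxn.stoichiometry:
                index.setdefault(cid, set()).add(rid)
        return index


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    ec_numbers: frozenset[str]

    def __post_init__(self):
        if not self.ec_numbers:
            raise UniverseValidationError(f"gene {self.gene_id} has no EC numbers")


# ---------------------------------------------------------------------------
# Formula and equation parsing
# ---------------------------------------------------------------------------


def parse_formula(text: str) -> Optional[dict[str, int]]:
    """Parse a Hill-style formula string; ``-`` = known empty, "" = unknown."""
    text = text.strip()
    if text == "":
        return None
    if text == "-":
        return {}
    out: dict[str, int] = {}
    pos = 0
    for m in FORMULA_TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"unparsable formula {text!r}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(text):
        raise ValueError(f"unparsable formula {text!r}")
    return out


def format_formula(formula: Optional[dict[str, int]]) -> str:
    if formula is None:
        return ""
    if not formula:
        return "-"
    return "".join(
        f"{el}{n if n != 1 else ''}" for el, n in sorted(formula.items())
    )


_COEF_RE = re.compile(r"^(\d+(?:/\d+)?|\d*\.\d+)$")


def parse_equation(equation: str) -> tuple[dict[str, Fraction], str, bool, bool]:
    """Parse ``2 A + B <=> C`` into (net stoichiometry, direction,
    symbolic_coefficient, incomplete).

    Species occurring on both sides are merged; if everything cancels the
    reaction is flagged incomplete (its net conversion is empty).
    """
    if "<=>" in equation:
        lhs, rhs = equation.split("<=>", 1)
        direction = "reversible"
    elif "=>" in equation:
        lhs, rhs = equation.split("=>", 1)
        direction = "forward"
    else:
        raise ValueError(f"equation lacks an arrow: {equation!r}")

    symbolic = False
    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> bool:
        nonlocal symbolic
        terms = [t.strip() for t in side.split(" + ")]
        terms = [t for t in terms if t]
        for term in terms:
            parts = term.split()
            if len(parts) == 1:
                coeff, cid = Fraction(1), parts[0]
            elif len(parts) == 2:
                tok, cid = parts
                if tok in ("m", "n"):
                    symbolic = True
                    coeff = Fraction(1)
                elif _COEF_RE.match(tok):
                    coeff = Fraction(tok)
                else:
                    raise ValueError(f"bad coefficient {tok!r} in {equation!r}")
            else:
                raise ValueError(f"bad term {term!r} in {equation!r}")
            stoich[cid] = stoich.get(cid, Fraction(0)) + sign * coeff
        return bool(terms)

    has_lhs = add_side(lhs, -1)
    has_rhs = add_side(rhs, +1)
    stoich = {c: v for c, v in stoich.items() if v != 0}
    incomplete = not (has_lhs and has_rhs) or not stoich
    return stoich, direction, symbolic, incomplete


def format_equation(stoich: dict[str, Fraction], direction: str) -> str:
    arrow = "<=>" if direction == "reversible" else "=>"

    def side(items):
        terms = []
        for cid, coeff in sorted(items):
            coeff = abs(coeff)
            terms.append(cid if coeff == 1 else f"{coeff} {cid}")
        return " + ".join(terms)

    lhs = side((c, v) for c, v in stoich.items() if v < 0)
    rhs = side((c, v) for c, v in stoich.items() if v > 0)
    return f"{lhs} {arrow} {rhs}"


# ---------------------------------------------------------------------------
# Flat-file parsing
# ---------------------------------------------------------------------------


def _read_tsv(path: Path, columns: list[str]) -> Iterable[tuple[int, dict[str, str]]]:
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < len(columns):
                row = row + [""] * (len(columns) - len(row))
            yield lineno, dict(zip(columns, row))


def _split_multi(text: str) -> set[str]:
    return {t.strip() for t in text.split(";") if t.strip()}


def parse_universe(
    compound_file: str | Path,
    reaction_file: str | Path,
    pathway_links: str | Path,
    enzyme_links: str | Path,
    generic_compounds: Optional[set[str]] = None,
) -> Universe:
    """Parse the four reference tables into a validated :class:`Universe`.

    Reactions touching a compound from *generic_compounds* (class compounds
    such as "an alcohol") are flagged generic at parse time.  Unparsable
    lines are logged with their line number and skipped.
    """
    generic_compounds = generic_compounds or set()
    uni = Universe()

    for lineno, row in _read_tsv(Path(compound_file), ["id", "name", "formula", "charge", "aliases"]):
        try:
            uni.compounds[row["id"].strip()] = Compound(
                id=row["id"].strip(),
                name=row["name"].strip(),
                formula=parse_formula(row["formula"]),
                charge=int(row["charge"]) if row["charge"].strip() else 0,
                aliases=_split_multi(row["aliases"]),
            )
        except (ValueError, UniverseValidationError) as exc:
            log.warning("%s line %d: skipping compound (%s)", compound_file, lineno, exc)

    for lineno, row in _read_tsv(
        Path(reaction_file),
        ["id", "equation", "direction", "ec_numbers", "main_reaction_id", "pathways", "subsystem"],
    ):
        rid = row["id"].strip()
        try:
            stoich, eq_direction, symbolic, incomplete = parse_equation(row["equation"])
            direction = row["direction"].strip() or eq_direction
            flags = ReactionFlags(
                generic=bool(set(stoich) & generic_compounds),
                incomplete=incomplete,
                symbolic_coefficient=symbolic,
            )
            uni.reactions[rid] = ReactionRecord(
                id=rid,
                stoichiometry=stoich,
                direction=direction,
                ec_numbers=_split_multi(row["ec_numbers"]),
                main_reaction_id=row["main_reaction_id"].strip() or None,
                pathways=_split_multi(row["pathways"]),
                subsystem=row["subsystem"].strip() or None,
                flags=flags,
            )
        except (ValueError, UniverseValidationError) as exc:
            log.warning("%s line %d: skipping reaction (%s)", reaction_file, lineno, exc)

    for lineno, row in _read_tsv(Path(pathway_links), ["pathway_id", "subsystem"]):
        uni.pathway_to_subsystem[row["pathway_id"].strip()] = row["subsystem"].strip()

    for lineno, row in _read_tsv(Path(enzyme_links), ["ec", "reaction_id"]):
        ec, rid = row["ec"].strip(), row["reaction_id"].strip()
        if rid not in uni.reactions:
            log.warning("%s line %d: EC %s links unknown reaction %s; skipped",
                        enzyme_links, lineno, ec, rid)
            continue
        uni.ec_to_reactions.setdefault(ec, set()).add(rid)

    # union in the ECs declared on the reaction records themselves
    for rid, rxn in uni.reactions.items():
        for ec in rxn.ec_numbers:
            uni.ec_to_reactions.setdefault(ec, set()).add(rid)

    uni.validate()
    return uni


def parse_annotations(annotation_file: str | Path) -> set[GeneAnnotation]:
    """Parse the two-column gene/EC table, grouping rows per gene and
    collapsing duplicate (gene, EC) pairs."""
    per_gene: dict[str, set[str]] = {}
    for lineno, row in _read_tsv(Path(annotation_file), ["gene_id", "ec"]):
        gene, ec = row["gene_id"].strip(), row["ec"].strip()
        if not EC_RE.match(ec):
            log.warning("%s line %d: malformed EC %r; skipped", annotation_file, lineno, ec)
            continue
        per_gene.setdefault(gene, set()).add(ec)
    return {
        GeneAnnotation(gene_id=g, ec_numbers=frozenset(ecs))
        for g, ecs in per_gene.items()
    }


# ---------------------------------------------------------------------------
# Model JSON serialization
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "id": model.id,
        "objective": model.objective,
        "metabolites": [
            {
                "compound_id": m.compound_id,
                "compartment": m.compartment,
                "name": m.name,
                "formula": dict(m.formula) if m.formula is not None else None,
                "charge": m.charge,
            }
            for _, m in sorted(model.metabolites.items())
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "kind": r.kind,
                "gpr": r.gpr.to_json() if r.gpr is not None else None,
                "pathways": sorted(r.pathways),
                "subsystem": r.subsystem,
                "tags": sorted(r.tags),
            }
            for _, r in sorted(model.reactions.items())
        ],
    }


def model_from_dict(data: dict) -> MetabolicModel:
    if data.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {data.get('schema_version')!r}")
    model = MetabolicModel(id=data.get("id", "model"), objective=data.get("objective"))
    for m in data["metabolites"]:
        model.add_metabolite(
            Metabolite(
                compound_id=m["compound_id"],
                compartment=m["compartment"],
                name=m.get("name", ""),
                formula=m.get("formula"),
                charge=m.get("charge", 0),
            )
        )
    for r in data["reactions"]:
        model.add_reaction(
            ModelReaction(
                id=r["id"],
                stoichiometry=r["stoichiometry"],
                lower_bound=r["lower_bound"],
                upper_bound=r["upper_bound"],
                kind=r["kind"],
                gpr=GPR.from_json(r["gpr"]) if r.get("gpr") is not None else None,
                pathways=set(r.get("pathways", [])),
                subsystem=r.get("subsystem"),
                tags=set(r.get("tags", [])),
            )
        )
    return model


def write_model(model: MetabolicModel, path: str | Path, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1)
            fh.write("\n")
    elif fmt == "sbml":
        from gsmforge import _sbml

        _sbml.write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# Universe JSON serialization (CLI stage hand-off)
# ---------------------------------------------------------------------------


def _record_to_dict(record: ReactionRecord) -> dict:
    return {
        "id": record.id,
        "stoichiometry": {c: str(v) for c, v in sorted(record.stoichiometry.items())},
        "direction": record.direction,
        "ec_numbers": sorted(record.ec_numbers),
        "main_reaction_id": record.main_reaction_id,
        "pathways": sorted(record.pathways),
        "subsystem": record.subsystem,
        "flags": vars(record.flags),
    }


def _record_from_dict(data: dict) -> ReactionRecord:
    return ReactionRecord(
        id=data["id"],
        stoichiometry={c: Fraction(v) for c, v in data["stoichiometry"].items()},
        direction=data["direction"],
        ec_numbers=set(data["ec_numbers"]),
        main_reaction_id=data.get("main_reaction_id"),
        pathways=set(data["pathways"]),
        subsystem=data.get("subsystem"),
        flags=ReactionFlags(**data["flags"]),
    )


def universe_to_dict(universe: Universe) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "compounds": [
            {
                "id": c.id, "name": c.name,
                "formula": dict(c.formula) if c.formula is not None else None,
                "charge": c.charge, "aliases": sorted(c.aliases),
            }
            for _, c in sorted(universe.compounds.items())
        ],
        "reactions": [_record_to_dict(r) for _, r in sorted(universe.reactions.items())],
        "ec_to_reactions": {
            ec: sorted(rids) for ec, rids in sorted(universe.ec_to_reactions.items())
        },
        "pathway_to_subsystem": dict(sorted(universe.pathway_to_subsystem.items())),
    }


def universe_from_dict(data: dict) -> Universe:
    uni = Universe(
        compounds={
            c["id"]: Compound(
                id=c["id"], name=c["name"], formula=c["formula"],
                charge=c["charge"], aliases=set(c["aliases"]),
            )
            for c in data["compounds"]
        },
        reactions={r["id"]: _record_from_dict(r) for r in data["reactions"]},
        ec_to_reactions={ec: set(v) for ec, v in data["ec_to_reactions"].items()},
        pathway_to_subsystem=dict(data["pathway_to_subsystem"]),
    )
    uni.validate()
    return uni


def write_universe(universe: Universe, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(universe_to_dict(universe), fh, indent=1)
        fh.write("\n")


def read_universe(path: str | Path) -> Universe:
    with open(path) as fh:
        return universe_from_dict(json.load(fh))


def read_model(path: str | Path, format: Optional[str] = None) -> MetabolicModel:
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    if fmt == "json":
        with open(path) as fh:
            return model_from_dict(json.load(fh))
    elif fmt == "sbml":
        from gsmforge import _sbml

        return _sbml.read_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")
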