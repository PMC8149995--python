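"""SBML Level 3 (+fbc v2) export/import for MetabolicModel.

Bounds, the objective and gene associations use the fbc package; fields SBML
has no slot for (reaction kind, pathways, subsystem, tags, formula of
species with unknown composition) ride in structured notes, so that
read(write(m)) is lossless.
"""

from __future__ import annotations

import re
from pathlib import Path

import libsbml

from gsmforge.model import GPR, MetabolicModel, Metabolite, ModelReaction
from gsmforge.universe_io import format_formula, parse_formula

_SID_OK = re.compile(r"[A-Za-z0-9_]")


def _sanitize(raw: str) -> str:
    out = []
    for ch in raw:
        out.append(ch if _SID_OK.match(ch) else f"__{ord(ch)}__")
    text = "".join(out)
    if not text or text[0].isdigit():
        text = "_" + text
    return text


def _unsanitize(text: str) -> str:
    if text.startswith("_") and len(text) > 1 and text[1].isdigit():
        text = text[1:]
    return re.sub(r"__(\d+)__", lambda m: chr(int(m.group(1))), text)


def _notes(pairs: dict[str, str]) -> str:
    body = "".join(f"<p>{k}: {v}</p>" for k, v in pairs.items())
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'


def _parse_notes(node) -> dict[str, str]:
    if node is None:
        return {}
    text = libsbml.XMLNode.convertXMLNodeToString(node)
    out = {}
    for m in re.finditer(r"<p>(.*?)</p>", text, re.S):
        if ": " in m.group(1):
            k, v = m.group(1).split(": ", 1)
            out[k.strip()] = v
        elif m.group(1).endswith(":"):
            out[m.group(1)[:-1].strip()] = ""
    return out


def _check(value, what: str):
    if value is None:
        raise RuntimeError(f"libsbml returned None while {what}")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise RuntimeError(f"libsbml error {value} while {what}")
    return value


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sanitize(model.id))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(False)

    for cid in ("c", "e"):
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)
        comp.setSize(1.0)

    for key, met in sorted(model.metabolites.items()):
        sp = sm.createSpecies()
        _check(sp.setId("M_" + _sanitize(key)), f"species id {key}")
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialConcentration(0.0)
        splug = sp.getPlugin("fbc")
        splug.setCharge(met.charge)
        if met.formula:
            splug.setChemicalFormula(format_formula(met.formula))
        sp.setNotes(_notes({
            "compound_id": met.compound_id,
            "formula": format_formula(met.formula),
            "charge": str(met.charge),
        }))

    bound_params: dict[float, str] = {}

    def bound_id(value: float) -> str:
        if value not in bound_params:
            pid = f"bnd_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    genes_seen: set[str] = set()

    def ensure_gene(gene: str) -> str:
        gid = "G_" + _sanitize(gene)
        if gene not in genes_seen:
            gp = mplug.createGeneProduct()
            _check(gp.setId(gid), f"gene product {gene}")
            gp.setLabel(gene)
            genes_seen.add(gene)
        return gid

    def build_assoc(parent, node):
        if isinstance(node, str):
            ref = parent.createGeneProductRef()
            _check(ref.setGeneProduct(ensure_gene(node)), f"gene ref {node}")
        else:
            op, children = node
            sub = parent.createAnd() if op == "and" else parent.createOr()
            for child in children:
                build_assoc(sub, child)

    for rid, rxn in sorted(model.reactions.items()):
        sr = sm.createReaction()
        _check(sr.setId("R_" + _sanitize(rid)), f"reaction id {rid}")
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for key, coeff in sorted(rxn.stoichiometry.items()):
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies("M_" + _sanitize(key))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_id(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_id(rxn.upper_bound))
        if rxn.gpr is not None:
            ga = rplug.createGeneProductAssociation()
            build_assoc(ga, rxn.gpr.expression)
        sr.setNotes(_notes({
            "kind": rxn.kind,
            "pathways": ";".join(sorted(rxn.pathways)),
            "subsystem": rxn.subsystem or "",
            "tags": ";".join(sorted(rxn.tags)),
        }))

    if model.objective is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + _sanitize(model.objective))
        fo.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise RuntimeError(f"failed to write SBML to {path}")


def _assoc_to_node(assoc, gene_labels: dict[str, str]):
    if isinstance(assoc, libsbml.GeneProductRef):
        return gene_labels[assoc.getGeneProduct()]
    op = "and" if isinstance(assoc, libsbml.FbcAnd) else "or"
    children = tuple(
        _assoc_to_node(assoc.getAssociation(i), gene_labels)
        for i in range(assoc.getNumAssociations())
    )
    return (op, children)


def read_sbml(path: str | Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ValueError(f"SBML parse errors in {path}: {doc.getErrorLog().toString()}")
    sm = doc.getModel()
    model = MetabolicModel(id=_unsanitize(sm.getId()))
    mplug = sm.getPlugin("fbc")

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        notes = _parse_notes(sp.getNotes())
        compound_id = notes.get("compound_id") or _unsanitize(sp.getId()[2:]).rsplit("_", 1)[0]
        model.add_metabolite(Metabolite(
            compound_id=compound_id,
            compartment=sp.getCompartment(),
            name=sp.getName(),
            formula=parse_formula(notes.get("formula", "")),
            charge=int(notes.get("charge", "0") or 0),
        ))

    gene_labels = {}
    for i in range(mplug.getNumGeneProducts()):
        gp = mplug.getGeneProduct(i)
        gene_labels[gp.getId()] = gp.getLabel() or _unsanitize(gp.getId()[2:])

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = _unsanitize(sr.getId()[2:])
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            key = _unsanitize(ref.getSpecies()[2:])
            stoich[key] = stoich.get(key, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            key = _unsanitize(ref.getSpecies()[2:])
            stoich[key] = stoich.get(key, 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        notes = _parse_notes(sr.getNotes())
        gpr = None
        ga = rplug.getGeneProductAssociation()
        if ga is not None and ga.getAssociation() is not None:
            gpr = GPR(_assoc_to_node(ga.getAssociation(), gene_labels))
        model.add_reaction(ModelReaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=params[rplug.getLowerFluxBound()],
            upper_bound=params[rplug.getUpperFluxBound()],
            kind=notes.get("kind", "metabolic"),
            gpr=gpr,
            pathways=set(filter(None, notes.get("pathways", "").split(";"))),
            subsystem=notes.get("subsystem") or None,
            tags=set(filter(None, notes.get("tags", "").split(";"))),
        ))

    obj = mplug.getActiveObjective()
    if obj is not None and obj.getNumFluxObjectives() > 0:
        model.objective = _unsanitize(obj.getFluxObjective(0).getReaction()[2:])
    return model
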