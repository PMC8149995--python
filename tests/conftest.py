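from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import pytest

from gsmforge import boundary_biomass, draft_network, fba_core, gapfill, refinement
from gsmforge import universe_io
from gsmforge.pipeline_cli import PipelineConfig, run_pipeline
from gsmforge.synthetic_data import GeneratorConfig, generate_universe

SEED = 1


@pytest.fixture(scope="session")
def world(tmp_path_factory):
    """The default synthetic study: emitted flat files plus ground truth."""
    out = tmp_path_factory.mktemp("world")
    paths, truth = generate_universe(GeneratorConfig(seed=SEED), out)
    return out, truth


@pytest.fixture(scope="session")
def ground_truth(world):
    return world[1]


@pytest.fixture(scope="session")
def universe(world):
    d, _ = world
    with open(d / "generic_compounds.tsv") as fh:
        generic = {r[0] for r in list(csv.reader(fh, delimiter="\t"))[1:] if r}
    return universe_io.parse_universe(
        d / "compounds.tsv", d / "reactions.tsv", d / "pathways.tsv",
        d / "enzymes.tsv", generic_compounds=generic,
    )


@pytest.fixture(scope="session")
def annotations(world):
    return universe_io.parse_annotations(world[0] / "genes.tsv")


@dataclass
class Staged:
    """All intermediate artifacts of one reconstruction, stage by stage."""

    universe: object
    annotations: object
    draft: object
    refined: object
    ref_report: object
    filled: object
    gap_report: object
    boundary_model: object  # before blocked-precursor repair
    model: object           # after repair
    repair_report: object
    classes: dict
    tables: dict
    molar_masses: dict
    targets: list


@pytest.fixture(scope="session")
def staged(world, universe, annotations) -> Staged:
    d, truth = world
    draft = draft_network.assemble_draft(universe, annotations)

    refined, report = refinement.balance_network(draft, universe)
    with open(d / "alias_policy.tsv") as fh:
        alias = {r[0]: r[1] for r in list(csv.reader(fh, delimiter="\t"))[1:] if r}
    refined, modified = refinement.standardize_chirality(refined, alias)
    report.modified_chirality_count = len(modified)
    refined, report = refinement.remove_redundant(refined, report)
    refined, report = refinement.supplement_metadata(refined, universe, report)

    filled, gap_report = gapfill.fill_gaps(refined, universe)

    classes: dict[str, list[str]] = {}
    with open(d / "nutrient_classes.tsv") as fh:
        for row in list(csv.reader(fh, delimiter="\t"))[1:]:
            classes.setdefault(row[0], []).append(row[1])

    model = boundary_biomass.network_to_model(filled, universe)
    model = boundary_biomass.add_boundary_reactions(model, classes)
    model = boundary_biomass.apply_bounds_policy(
        model,
        synthesizable=set(classes.get("cofactors", [])),
        trace_elements=set(classes.get("minerals", [])),
    )

    varieties = sorted({
        row["variety"]
        for row in csv.DictReader(open(d / "compositions.tsv"), delimiter="\t")
    })
    tables = {
        v: boundary_biomass.read_composition_table(d / "compositions.tsv", v)
        for v in varieties
    }
    class_compounds = {c for cids in classes.values() for c in cids}
    targets = sorted({
        e.compound_id for t in tables.values() for e in t.entries
    } - class_compounds)

    repaired, repair_report = fba_core.diagnose_and_repair(model, targets, universe)
    molar_masses = boundary_biomass.load_molar_masses(d / "molar_masses.tsv")
    return Staged(
        universe=universe, annotations=annotations, draft=draft,
        refined=refined, ref_report=report,
        filled=filled, gap_report=gap_report,
        boundary_model=model, model=repaired, repair_report=repair_report,
        classes=classes, tables=tables, molar_masses=molar_masses,
        targets=targets,
    )


@pytest.fixture(scope="session")
def variety_model(staged):
    """The repaired model carrying one variety's biomass equation."""
    variety = sorted(staged.tables)[0]
    equation = boundary_biomass.build_biomass_equation(
        staged.tables[variety], staged.molar_masses)
    return boundary_biomass.attach_biomass(staged.model, equation)


@pytest.fixture(scope="session")
def pipeline_run(world, tmp_path_factory):
    d, _ = world
    out = tmp_path_factory.mktemp("pipeline")
    report = run_pipeline(PipelineConfig(universe_dir=str(d), out_dir=str(out), seed=SEED))
    return report, out


# ---------------------------------------------------------------------------
# Small hand-made fixtures
# ---------------------------------------------------------------------------


def make_universe(compounds, reactions, pathway_to_subsystem=None):
    """Build an in-memory Universe from Compound / ReactionRecord lists."""
    uni = universe_io.Universe(
        compounds={c.id: c for c in compounds},
        reactions={r.id: r for r in reactions},
        pathway_to_subsystem=pathway_to_subsystem or {},
    )
    for rid, rec in uni.reactions.items():
        for ec in rec.ec_numbers:
            uni.ec_to_reactions.setdefault(ec, set()).add(rid)
    uni.validate()
    return uni


def make_network(records):
    """Wrap ReactionRecords into a DraftNetwork with empty gene data."""
    net = draft_network.DraftNetwork()
    for rec in records:
        net.reactions[rec.id] = draft_network.DraftEntry(
            record=rec, gpr=None, genes=frozenset(), enzymes=frozenset())
    return net
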