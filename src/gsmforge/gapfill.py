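"""Gap filling over weakly connected components (WCCs).

The network is viewed as an undirected bipartite graph of reactions and the
metabolites they touch; ubiquitous currency metabolites (water, ATP, NAD...)
are excluded from edges, otherwise they connect everything and the partition
collapses to one component.  A gap reaction is a universe reaction, absent
from the network, whose metabolites touch at least two components; adding it
merges them.  Filling is greedy (most components merged first, then smallest
id) and runs at pathway scale (candidates must share a pathway with the
components they join) before global scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

from gsmforge.draft_network import DraftEntry, DraftNetwork
from gsmforge.universe_io import Universe

log = logging.getLogger(__name__)

#: Default currency metabolites excluded from connectivity edges: water,
#: proton, ATP, ADP, phosphate, NAD(H), NADP(H), CO2, O2, electron.
DEFAULT_CURRENCY = {
    "C00001", "C00080", "C00002", "C00008", "C00009",
    "C00003", "C00004", "C00005", "C00006",
    "C00011", "C00007", "C05359",
}


@dataclass
class WccPartition:
    components: list[set[str]] = field(default_factory=list)  # reaction-id sets
    metabolite_assignment: dict[str, int] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.components)


@dataclass
class GapReport:
    wcc_before: int = 0
    wcc_after: int = 0
    added: list[tuple[str, str]] = field(default_factory=list)  # (rid, scale)


def _participants(network: DraftNetwork) -> dict[str, set[str]]:
    return {
        rid: set(entry.record.stoichiometry)
        for rid, entry in network.reactions.items()
    }


def compute_wccs(
    participants: Mapping[str, Iterable[str]],
    currency_excluded: Optional[set[str]] = None,
) -> WccPartition:
    """Partition the reaction/metabolite bipartite graph into weakly
    connected components, ordered by smallest contained reaction id."""
    currency = DEFAULT_CURRENCY if currency_excluded is None else currency_excluded
    graph = nx.Graph()
    for rid, mets in participants.items():
        rnode = ("R", rid)
        graph.add_node(rnode)
        for cid in mets:
            if cid in currency:
                continue
            graph.add_edge(rnode, ("M", cid))

    raw = [
        comp for comp in nx.connected_components(graph)
        if any(kind == "R" for kind, _ in comp)
    ]
    raw.sort(key=lambda comp: min(name for kind, name in comp if kind == "R"))
    partition = WccPartition()
    for idx, comp in enumerate(raw):
        partition.components.append({name for kind, name in comp if kind == "R"})
        for kind, name in comp:
            if kind == "M":
                partition.metabolite_assignment[name] = idx
    return partition


def _component_pathways(
    partition: WccPartition, network: DraftNetwork
) -> list[set[str]]:
    out = []
    for comp in partition.components:
        pws: set[str] = set()
        for rid in comp:
            pws |= network.reactions[rid].record.pathways
        out.append(pws)
    return out


def find_gap_candidates(
    network: DraftNetwork,
    universe: Universe,
    scale: str,
    partition: Optional[WccPartition] = None,
    currency_excluded: Optional[set[str]] = None,
) -> list[tuple[str, int]]:
    """Universe reactions absent from the network that would merge >= 2
    components, as (reaction id, number of components merged), sorted by
    (merged desc, id asc).

    At pathway scale only components sharing a pathway with the candidate
    count toward the merge."""
    if scale not in ("pathway", "global"):
        raise ValueError(f"unknown gap-filling scale {scale!r}")
    currency = DEFAULT_CURRENCY if currency_excluded is None else currency_excluded
    if partition is None:
        partition = compute_wccs(_participants(network), currency)
    comp_pathways = _component_pathways(partition, network)

    candidates: list[tuple[str, int]] = []
    for rid in sorted(universe.reactions):
        if rid in network.reactions:
            continue
        record = universe.reactions[rid]
        touched = {
            partition.metabolite_assignment[cid]
            for cid in record.stoichiometry
            if cid not in currency and cid in partition.metabolite_assignment
        }
        if scale == "pathway":
            touched = {
                idx for idx in touched
                if record.pathways and record.pathways & comp_pathways[idx]
            }
        if len(touched) >= 2:
            candidates.append((rid, len(touched)))
    candidates.sort(key=lambda item: (-item[1], item[0]))
    return candidates


def fill_gaps(
    network: DraftNetwork,
    universe: Universe,
    currency_excluded: Optional[set[str]] = None,
) -> tuple[DraftNetwork, GapReport]:
    """Greedy two-phase gap filling: pathway scale until exhausted, then
    global scale.  Added reactions carry no gene association and are tagged
    via ``flags``-free bookkeeping in the report (they are hypothesized, not
    annotated)."""
    currency = DEFAULT_CURRENCY if currency_excluded is None else currency_excluded
    out = network.copy()
    report = GapReport()
    report.wcc_before = compute_wccs(_participants(out), currency).count

    for scale in ("pathway", "global"):
        while True:
            partition = compute_wccs(_participants(out), currency)
            candidates = find_gap_candidates(out, universe, scale, partition, currency)
            if not candidates:
                break
            rid, merged = candidates[0]
            record = universe.reactions[rid].copy()
            out.reactions[rid] = DraftEntry(
                record=record, gpr=None, genes=frozenset(), enzymes=frozenset()
            )
            report.added.append((rid, scale))
            after = compute_wccs(_participants(out), currency).count
            log.debug("gapfill[%s]: added %s (merged %d components -> %d WCCs)",
                      scale, rid, merged, after)

    report.wcc_after = compute_wccs(_participants(out), currency).count
    log.info("gap filling: %d -> %d WCCs, %d reactions added",
             report.wcc_before, report.wcc_after, len(report.added))
    return out, report
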