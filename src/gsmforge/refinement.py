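"""Network refinement: balancing, chirality, redundancy, metadata.

Balancing follows element and charge conservation: the per-element deficit
of a reaction is the signed sum of coefficient x element count over all
species (products positive).  Unbalanced reactions are repaired by adding
integer multiples of small filler species (water, proton, electron, methane,
ethylene by default), choosing the solution with the smallest total filler
count; chirality is standardized through an alias policy (e.g. D-glucose ->
alpha-D-glucose); step reactions shadowed by a total reaction, generic
(class-compound) reactions, incomplete/symbolic-coefficient reactions and
chiral duplicates are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import LinearConstraint, milp

from gsmforge.draft_network import DraftNetwork
from gsmforge.universe_io import Compound, ReactionRecord, Universe

log = logging.getLogger(__name__)

#: Default filler species tried during balancing, in preference order:
#: water, proton, electron, methane, ethylene (KEGG accessions).
DEFAULT_FILLERS = ["C00001", "C00080", "C05359", "C01438", "C06547"]

MAX_FILLER_COEFF = 10


@dataclass
class ImbalanceReport:
    """Signed products-minus-substrates deficit per element, plus charge."""

    element_deficit: dict[str, Fraction] = field(default_factory=dict)
    charge_deficit: Fraction = Fraction(0)
    computable: bool = True  # False when a species lacks a formula

    @property
    def balanced(self) -> bool:
        return (
            self.computable
            and all(v == 0 for v in self.element_deficit.values())
            and self.charge_deficit == 0
        )


@dataclass
class RefinementReport:
    balanced_count: int = 0
    unbalanceable: list[str] = field(default_factory=list)
    balance_fixes: dict[str, dict[str, Fraction]] = field(default_factory=dict)
    modified_chirality_count: int = 0
    removed: dict[str, list[str]] = field(default_factory=lambda: {
        "step": [], "generic": [], "incomplete_or_symbolic": [], "chiral_duplicate": [],
    })
    metadata_supplemented_count: int = 0


def check_balance(
    reaction: ReactionRecord, compounds: Mapping[str, Compound]
) -> ImbalanceReport:
    """Element/charge deficit of a reaction (all-zero iff balanced)."""
    report = ImbalanceReport()
    for cid, coeff in reaction.stoichiometry.items():
        compound = compounds.get(cid)
        if compound is None or compound.formula is None:
            report.computable = False
            continue
        for el, n in compound.formula.items():
            report.element_deficit[el] = (
                report.element_deficit.get(el, Fraction(0)) + coeff * n
            )
        report.charge_deficit += coeff * compound.charge
    report.element_deficit = {
        el: v for el, v in report.element_deficit.items() if v != 0
    }
    return report


def balance_reaction(
    reaction: ReactionRecord,
    compounds: Mapping[str, Compound],
    fillers: Optional[Sequence[str]] = None,
) -> tuple[ReactionRecord, Optional[dict[str, Fraction]]]:
    """Balance a reaction by adding integer filler multiples to either side.

    Searches coefficients in [-MAX_FILLER_COEFF, MAX_FILLER_COEFF] per
    filler, minimizing the total filler count (ties broken by filler list
    order).  Returns (reaction, fix) where *fix* maps filler id -> signed
    added coefficient; fix is ``{}`` if already balanced and ``None`` if no
    combination balances the reaction (flags.unbalanceable is then set).
    """
    fillers = list(fillers) if fillers is not None else list(DEFAULT_FILLERS)
    report = check_balance(reaction, compounds)
    if report.balanced:
        return reaction, {}
    if not report.computable:
        out = reaction.copy()
        out.flags.unbalanceable = True
        return out, None

    filler_comps = [compounds[f] for f in fillers if f in compounds]
    fillers = [c.id for c in filler_comps]
    rows = sorted(report.element_deficit) + ["__charge__"]
    # also constrain elements the fillers could disturb
    for c in filler_comps:
        for el in (c.formula or {}):
            if el not in rows:
                rows.insert(-1, el)

    A = np.zeros((len(rows), len(fillers)))
    b = np.zeros(len(rows))
    for i, row in enumerate(rows):
        if row == "__charge__":
            b[i] = -float(report.charge_deficit)
            for j, c in enumerate(filler_comps):
                A[i, j] = c.charge
        else:
            b[i] = -float(report.element_deficit.get(row, Fraction(0)))
            for j, c in enumerate(filler_comps):
                A[i, j] = (c.formula or {}).get(row, 0)

    n = len(fillers)
    if n == 0:
        out = reaction.copy()
        out.flags.unbalanceable = True
        return out, None
    # variables: x (signed coefficients), t >= |x|; minimize sum of t with a
    # tiny order-dependent weight so ties resolve toward earlier fillers
    c_obj = np.concatenate([np.zeros(n), 1.0 + 1e-6 * np.arange(n)])
    A_eq = np.hstack([A, np.zeros_like(A)])
    # t - x >= 0 and t + x >= 0
    A_abs = np.vstack([
        np.hstack([-np.eye(n), np.eye(n)]),
        np.hstack([np.eye(n), np.eye(n)]),
    ])
    constraints = [
        LinearConstraint(A_eq, b, b),
        LinearConstraint(A_abs, 0, np.inf),
    ]
    integrality = np.ones(2 * n)
    lb = np.concatenate([-MAX_FILLER_COEFF * np.ones(n), np.zeros(n)])
    ub = MAX_FILLER_COEFF * np.ones(2 * n)
    res = milp(
        c_obj,
        constraints=constraints,
        integrality=integrality,
        bounds=(lb, ub),
    )
    if not res.success:
        out = reaction.copy()
        out.flags.unbalanceable = True
        return out, None

    x = np.round(res.x[:n]).astype(int)
    fix = {fillers[j]: Fraction(int(x[j])) for j in range(n) if x[j] != 0}
    out = reaction.copy()
    for cid, add in fix.items():
        new = out.stoichiometry.get(cid, Fraction(0)) + add
        if new == 0:
            out.stoichiometry.pop(cid, None)
        else:
            out.stoichiometry[cid] = new
    assert check_balance(out, compounds).balanced, reaction.id
    return out, fix


# ---------------------------------------------------------------------------
# Chirality
# ---------------------------------------------------------------------------


def resolve_alias_policy(alias_policy: Mapping[str, str]) -> dict[str, str]:
    """Resolve alias chains to their terminal canonical ids; a cycle in the
    policy is a fatal validation error."""
    resolved: dict[str, str] = {}
    for start in alias_policy:
        seen = [start]
        cur = start
        while cur in alias_policy:
            cur = alias_policy[cur]
            if cur in seen:
                raise ValueError(f"alias cycle in policy: {' -> '.join(seen + [cur])}")
            seen.append(cur)
        resolved[start] = cur
    return resolved


def standardize_chirality(
    network: DraftNetwork, alias_policy: Mapping[str, str]
) -> tuple[DraftNetwork, list[str]]:
    """Replace aliased compound ids by their canonical form everywhere.

    Returns the rewritten network and the list of reactions whose equations
    changed.  Reactions that become self-identical (substrates == products
    after substitution) and reactions that become copies of another reaction
    are flagged ``chiral_duplicate`` for later removal.
    """
    policy = resolve_alias_policy(alias_policy)
    out = network.copy()
    modified: list[str] = []

    for rid in sorted(out.reactions):
        record = out.reactions[rid].record
        if not set(record.stoichiometry) & set(policy):
            continue
        subs_before = {policy.get(c, c) for c in record.substrates}
        prods_before = {policy.get(c, c) for c in record.products}
        new_stoich: dict[str, Fraction] = {}
        for cid, coeff in record.stoichiometry.items():
            canon = policy.get(cid, cid)
            new_stoich[canon] = new_stoich.get(canon, Fraction(0)) + coeff
        record.stoichiometry = {c: v for c, v in new_stoich.items() if v != 0}
        modified.append(rid)
        if subs_before and subs_before == prods_before:
            record.flags.chiral_duplicate = True

    # cross-reaction duplicates created by the substitution: keep the
    # lexicographically smallest id of each identical stoichiometry group
    signature: dict[tuple, str] = {}
    for rid in sorted(out.reactions):
        record = out.reactions[rid].record
        if record.flags.chiral_duplicate or not record.stoichiometry:
            continue
        sig = (record.direction, tuple(sorted(record.stoichiometry.items())))
        keeper = signature.get(sig)
        if keeper is None:
            signature[sig] = rid
        elif rid in modified or keeper in modified:
            record.flags.chiral_duplicate = True
    return out, modified


# ---------------------------------------------------------------------------
# Redundancy removal
# ---------------------------------------------------------------------------


def _find_step_pairs(network: DraftNetwork) -> set[str]:
    """Reaction ids of step pairs shadowed by an existing total reaction.

    A pair (r1, r2) qualifies when an intermediate B is produced by r1 and
    consumed by r2, occurs in no other reaction (no branch), cancels exactly,
    and the summed stoichiometry equals some other reaction's stoichiometry.
    """
    occurs: dict[str, set[str]] = {}
    for rid, entry in network.reactions.items():
        for cid in entry.record.stoichiometry:
            occurs.setdefault(cid, set()).add(rid)

    signatures = {}
    for rid, entry in network.reactions.items():
        signatures[tuple(sorted(entry.record.stoichiometry.items()))] = rid

    removed: set[str] = set()
    for cid, rids in sorted(occurs.items()):
        if len(rids) != 2:
            continue
        r1, r2 = sorted(rids)
        s1 = network.reactions[r1].record.stoichiometry
        s2 = network.reactions[r2].record.stoichiometry
        if s1.get(cid, 0) + s2.get(cid, 0) != 0:
            continue
        # orient: the producer of the intermediate first
        net: dict[str, Fraction] = {}
        for s in (s1, s2):
            for c, v in s.items():
                net[c] = net.get(c, Fraction(0)) + v
        net = {c: v for c, v in net.items() if v != 0}
        total = signatures.get(tuple(sorted(net.items())))
        if total is not None and total not in (r1, r2):
            removed.update((r1, r2))
    return removed


def remove_redundant(
    network: DraftNetwork, report: Optional[RefinementReport] = None
) -> tuple[DraftNetwork, RefinementReport]:
    """Drop step pairs shadowed by a total reaction, generic reactions,
    incomplete or symbolic-coefficient reactions, and chiral duplicates."""
    report = report or RefinementReport()
    out = network.copy()
    step_ids = _find_step_pairs(out)
    for rid in sorted(out.reactions):
        flags = out.reactions[rid].record.flags
        if rid in step_ids:
            category = "step"
        elif flags.generic:
            category = "generic"
        elif flags.incomplete or flags.symbolic_coefficient:
            category = "incomplete_or_symbolic"
        elif flags.chiral_duplicate:
            category = "chiral_duplicate"
        else:
            continue
        report.removed[category].append(rid)
        del out.reactions[rid]
    log.info(
        "removed %d redundant reactions: %s",
        sum(len(v) for v in report.removed.values()),
        {k: len(v) for k, v in report.removed.items()},
    )
    return out, report


# ---------------------------------------------------------------------------
# Metadata supplementation
# ---------------------------------------------------------------------------


def supplement_metadata(
    network: DraftNetwork, universe: Universe, report: Optional[RefinementReport] = None
) -> tuple[DraftNetwork, RefinementReport]:
    """Fill missing main-reaction / pathway / subsystem fields.

    Missing values are inherited from the universe record; a reaction with
    no pathway anywhere may inherit the intersection of its metabolites'
    pathways; subsystems follow from the pathway->subsystem link table.
    """
    report = report or RefinementReport()
    out = network.copy()

    met_pathways: dict[str, set[str]] = {}
    for rec in universe.reactions.values():
        for cid in rec.stoichiometry:
            met_pathways.setdefault(cid, set()).update(rec.pathways)

    for rid in sorted(out.reactions):
        record = out.reactions[rid].record
        uni = universe.reactions.get(rid)
        touched = False
        if record.main_reaction_id is None and uni is not None and uni.main_reaction_id:
            record.main_reaction_id = uni.main_reaction_id
            touched = True
        if not record.pathways:
            if uni is not None and uni.pathways:
                record.pathways = set(uni.pathways)
                touched = True
            else:
                shared: Optional[set[str]] = None
                for cid in record.stoichiometry:
                    pws = met_pathways.get(cid, set())
                    shared = set(pws) if shared is None else shared & pws
                if shared:
                    record.pathways = shared
                    touched = True
        if record.subsystem is None:
            for pw in sorted(record.pathways):
                ss = universe.pathway_to_subsystem.get(pw)
                if ss:
                    record.subsystem = ss
                    touched = True
                    break
        if touched:
            report.metadata_supplemented_count += 1
    return out, report


def balance_network(
    network: DraftNetwork,
    universe: Universe,
    fillers: Optional[Sequence[str]] = None,
    report: Optional[RefinementReport] = None,
) -> tuple[DraftNetwork, RefinementReport]:
    """Run balance_reaction over every balance-checkable network reaction."""
    report = report or RefinementReport()
    out = network.copy()
    for rid in sorted(out.reactions):
        record = out.reactions[rid].record
        if record.flags.incomplete:
            continue
        fixed, fix = balance_reaction(record, universe.compounds, fillers)
        out.reactions[rid].record = fixed
        if fix is None:
            report.unbalanceable.append(rid)
        elif fix:
            report.balanced_count += 1
            report.balance_fixes[rid] = fix
    return out, report
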