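"""Flux balance analysis core.

Builds the sparse stoichiometric system S (metabolites x reactions), solves
``optimize c.v subject to S.v = 0, lb <= v <= ub`` with the HiGHS LP solver,
and layers the reconstruction's diagnostics on top: maximal synthesis flux
of single compounds, bounded repair search for blocked precursors, maximum
growth, and nutrient-requirement profiles at fixed growth.

Because FBA optima are typically degenerate, requirement profiles report a
parsimonious solution (minimum total absolute flux at the fixed biomass
flux) together with per-exchange flux-variability ranges, rather than one
arbitrary LP vertex.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from gsmforge.model import MetabolicModel, Metabolite, ModelReaction, met_key
from gsmforge.universe_io import ReactionRecord, Universe

log = logging.getLogger(__name__)

FEAS_TOL = 1e-9
FLUX_TOL = 1e-6


@dataclass
class StoichiometricSystem:
    S: sp.csr_matrix
    metabolite_ids: list[str]
    reaction_ids: list[str]
    lb: np.ndarray
    ub: np.ndarray
    objective: np.ndarray  # coefficient per reaction

    def summary(self) -> dict:
        nnz = self.S.nnz
        rows, cols = self.S.shape
        return {
            "metabolites": rows,
            "reactions": cols,
            "nonzeros": nnz,
            "density": nnz / (rows * cols) if rows and cols else 0.0,
        }


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded | failed
    objective_value: float = 0.0
    fluxes: dict[str, float] = field(default_factory=dict)
    residual: float = 0.0

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class RequirementProfile:
    """Per-nutrient exchange fluxes at a fixed biomass flux (negative =
    uptake) with flux-variability ranges exposing alternate optima."""

    variety: str
    biomass_flux: float
    exchange_fluxes: dict[str, float] = field(default_factory=dict)
    fva: dict[str, tuple[float, float]] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    classes: dict[str, str] = field(default_factory=dict)


def build_matrix(model: MetabolicModel, objective: Optional[str] = None) -> StoichiometricSystem:
    """Exact sparse mapping of model stoichiometry and bounds, rows/columns
    in sorted id order."""
    met_ids = sorted(model.metabolites)
    rxn_ids = sorted(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for key, coeff in model.reactions[rid].stoichiometry.items():
            if key not in met_index:
                raise ValueError(f"reaction {rid} references unknown metabolite {key}")
            rows.append(met_index[key])
            cols.append(j)
            vals.append(coeff)
    S = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)), dtype=float
    )
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    if np.any(lb > ub):
        raise ValueError("lower bound exceeds upper bound")
    c = np.zeros(len(rxn_ids))
    target = objective if objective is not None else model.objective
    if target is not None:
        c[rxn_ids.index(target)] = 1.0
    return StoichiometricSystem(S, met_ids, rxn_ids, lb, ub, c)


_STATUS = {0: "optimal", 1: "failed", 2: "infeasible", 3: "unbounded", 4: "failed"}


def solve_fba(system: StoichiometricSystem, sense: str = "max") -> FluxSolution:
    """Solve the steady-state LP; never silently returns zero on solver
    failure (the status is propagated)."""
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * system.objective,
        A_eq=system.S,
        b_eq=np.zeros(system.S.shape[0]),
        bounds=list(zip(system.lb, system.ub)),
        method="highs",
        options={"presolve": True},
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(status=status)
    v = res.x
    residual = float(np.max(np.abs(system.S @ v))) if v.size else 0.0
    return FluxSolution(
        status="optimal",
        objective_value=float(-res.fun if sense == "max" else res.fun),
        fluxes=dict(zip(system.reaction_ids, v.tolist())),
        residual=residual,
    )


def optimize(model: MetabolicModel, objective: str, sense: str = "max") -> FluxSolution:
    if objective not in model.reactions:
        raise ValueError(f"unknown objective reaction {objective!r}")
    return solve_fba(build_matrix(model, objective), sense)


# ---------------------------------------------------------------------------
# Synthesis diagnostics and repair
# ---------------------------------------------------------------------------

_SINK_PREFIX = "SYN_"


def _with_sink(model: MetabolicModel, compound_id: str) -> tuple[MetabolicModel, str]:
    """Return a copy with a secretion-only drain for the compound.

    An existing exchange for the compound is reused; otherwise a temporary
    (0, 1000) sink on the cytosolic species is added."""
    keys = [k for k, m in model.metabolites.items() if m.compound_id == compound_id]
    if not keys:
        raise ValueError(f"compound {compound_id!r} not in model")
    existing = model.exchange_for(compound_id)
    if existing is not None:
        return model.copy(), existing.id
    out = model.copy()
    key = met_key(compound_id, "c") if met_key(compound_id, "c") in model.metabolites else keys[0]
    sink = _SINK_PREFIX + compound_id
    out.reactions[sink] = ModelReaction(
        id=sink, stoichiometry={key: -1.0},
        lower_bound=0.0, upper_bound=1000.0,
        kind="exchange", tags={"temporary_sink"},
    )
    return out, sink


def max_synthesis_flux(model: MetabolicModel, compound_id: str) -> float:
    """FBA maximum of the compound's (possibly temporary) secretion
    exchange; 0 means the compound cannot be net-synthesized under the
    current medium."""
    probe, sink = _with_sink(model, compound_id)
    sol = optimize(probe, sink)
    if sol.status == "infeasible":
        raise RuntimeError(f"synthesis probe for {compound_id} infeasible")
    return max(sol.objective_value, 0.0)


def _record_to_model_reaction(
    record: ReactionRecord, universe: Universe, model: MetabolicModel
) -> ModelReaction:
    stoich = {}
    for cid, coeff in record.stoichiometry.items():
        compound = universe.compounds.get(cid)
        model.add_metabolite(Metabolite(
            compound_id=cid, compartment="c",
            name=compound.name if compound else "",
            formula=compound.formula if compound else None,
            charge=compound.charge if compound else 0,
        ))
        stoich[met_key(cid, "c")] = float(coeff)
    tags = {"repair"}
    if record.direction == "forward":
        tags.add("forward")
    return ModelReaction(
        id=record.id, stoichiometry=stoich,
        lower_bound=0.0 if record.direction == "forward" else -1000.0,
        upper_bound=1000.0,
        kind="metabolic", pathways=set(record.pathways),
        subsystem=record.subsystem, tags=tags,
    )


Edit = tuple[str, str]  # ("add", universe reaction id) | ("reverse", model reaction id)


def _apply_edit(model: MetabolicModel, edit: Edit, universe: Universe) -> None:
    op, rid = edit
    if op == "add":
        model.add_reaction(_record_to_model_reaction(
            universe.reactions[rid].copy(), universe, model))
    elif op == "reverse":
        rxn = model.reactions[rid]
        rxn.lower_bound, rxn.upper_bound = -rxn.upper_bound, -max(rxn.lower_bound, 0.0)
        rxn.tags.add("reversed")
    else:
        raise ValueError(f"unknown edit {edit!r}")


def _addition_candidates(
    model: MetabolicModel, universe: Universe, hops: int
) -> list[str]:
    """Universe reactions reachable from the model's compound set within
    the given number of shared-metabolite hops."""
    model_compounds = {m.compound_id for m in model.metabolites.values()}
    chosen: set[str] = set()
    frontier = set(model_compounds)
    for _ in range(max(hops, 1)):
        new_compounds: set[str] = set()
        for rid, record in universe.reactions.items():
            if rid in model.reactions or rid in chosen:
                continue
            if record.flags.incomplete or record.flags.symbolic_coefficient:
                continue
            if set(record.stoichiometry) & frontier:
                chosen.add(rid)
                new_compounds |= set(record.stoichiometry)
        frontier = new_compounds - model_compounds
        model_compounds |= new_compounds
        if not frontier:
            break
    return sorted(chosen)


@dataclass
class RepairReport:
    repaired: dict[str, list[Edit]] = field(default_factory=dict)
    already_ok: list[str] = field(default_factory=list)
    unrepaired: list[str] = field(default_factory=list)


def diagnose_and_repair(
    model: MetabolicModel,
    targets: Sequence[str],
    universe: Universe,
    max_additions: int = 3,
    candidate_cap: int = 20,
) -> tuple[MetabolicModel, RepairReport]:
    """Find minimal edit sets restoring synthesis of blocked targets.

    For each target with zero maximal synthesis flux, candidate edits are
    (a) universe reactions within ``max_additions`` shared-metabolite hops
    of the model and (b) direction reversals of irreversible model
    reactions.  Candidates that cannot carry flux toward the target in the
    fully relaxed super-model are pruned away; the survivors (capped at
    ``candidate_cap``) are searched breadth-first by edit-set size, so the
    first hit is a minimal repair."""
    out = model.copy()
    report = RepairReport()
    for target in targets:
        if not any(m.compound_id == target for m in out.metabolites.values()):
            # a fully disconnected target: give it a cytosolic species so
            # the synthesis probe (and candidate additions) can attach
            compound = universe.compounds.get(target)
            if compound is None:
                raise ValueError(f"repair target {target!r} unknown to the universe")
            out.add_metabolite(Metabolite(
                compound_id=target, compartment="c", name=compound.name,
                formula=compound.formula, charge=compound.charge,
            ))
        if max_synthesis_flux(out, target) > FLUX_TOL:
            report.already_ok.append(target)
            continue
        edits = _search_repair(out, target, universe, max_additions, candidate_cap)
        if edits is None:
            report.unrepaired.append(target)
            log.warning("target %s could not be repaired within %d edits",
                        target, max_additions)
        else:
            for edit in edits:
                _apply_edit(out, edit, universe)
            report.repaired[target] = list(edits)
            log.info("repaired %s with %s", target, edits)
    return out, report


def _search_repair(
    model: MetabolicModel,
    target: str,
    universe: Universe,
    max_additions: int,
    candidate_cap: int,
) -> Optional[list[Edit]]:
    additions = _addition_candidates(model, universe, hops=max_additions)
    reversals = [
        rid for rid, rxn in sorted(model.reactions.items())
        if rxn.kind == "metabolic" and rxn.lower_bound >= 0
    ]

    # relaxed super-model: all candidate additions present, all candidate
    # reversals made reversible
    relaxed = model.copy()
    for rid in additions:
        if rid not in relaxed.reactions:
            relaxed.add_reaction(_record_to_model_reaction(
                universe.reactions[rid].copy(), universe, relaxed))
    for rid in reversals:
        relaxed.reactions[rid].lower_bound = -relaxed.reactions[rid].upper_bound

    try:
        fmax = max_synthesis_flux(relaxed, target)
    except ValueError:
        return None
    if fmax <= FLUX_TOL:
        return None

    # pin a positive synthesis flux, then keep only candidates that can
    # actually carry flux under that requirement
    probe, sink = _with_sink(relaxed, target)
    probe.reactions[sink].lower_bound = min(1.0, fmax / 2.0)

    usable: list[Edit] = []
    for rid in additions:
        lo, hi = _flux_range(probe, rid)
        if hi > FLUX_TOL or lo < -FLUX_TOL:
            usable.append(("add", rid))
    for rid in reversals:
        lo, _ = _flux_range(probe, rid)
        if lo < -FLUX_TOL:
            usable.append(("reverse", rid))
    if len(usable) > candidate_cap:
        log.warning("repair search for %s: %d candidates, capping at %d",
                    target, len(usable), candidate_cap)
        usable = usable[:candidate_cap]

    for k in range(1, max_additions + 1):
        for combo in itertools.combinations(usable, k):
            trial = model.copy()
            for edit in combo:
                _apply_edit(trial, edit, universe)
            if max_synthesis_flux(trial, target) > FLUX_TOL:
                return list(combo)
    return None


def _flux_range(model: MetabolicModel, rid: str) -> tuple[float, float]:
    lo = optimize(model, rid, "min")
    hi = optimize(model, rid, "max")
    lo_v = lo.objective_value if lo.optimal else 0.0
    hi_v = hi.objective_value if hi.optimal else 0.0
    return lo_v, hi_v


# ---------------------------------------------------------------------------
# Growth and nutrient requirements
# ---------------------------------------------------------------------------


def _biomass_reaction(model: MetabolicModel) -> ModelReaction:
    biomass = model.reactions_of_kind("biomass")
    if len(biomass) != 1:
        raise ValueError(
            f"model must contain exactly one biomass reaction, found "
            f"{[r.id for r in biomass]}"
        )
    return biomass[0]


def max_growth(model: MetabolicModel) -> float:
    """FBA maximum of the biomass reaction flux (h^-1)."""
    sol = optimize(model, _biomass_reaction(model).id)
    if not sol.optimal:
        raise RuntimeError(f"growth LP not optimal: {sol.status}")
    return sol.objective_value


def parsimonious_fluxes(model: MetabolicModel) -> dict[str, float]:
    """Minimize total absolute flux subject to the current bounds (pFBA
    inner problem); the objective reaction should already be pinned."""
    system = build_matrix(model)
    n = len(system.reaction_ids)
    # split v = p - n with p, n >= 0
    A_eq = sp.hstack([system.S, -system.S]).tocsr()
    lb_p = np.maximum(system.lb, 0.0)
    ub_p = np.maximum(system.ub, 0.0)
    lb_n = np.maximum(-system.ub, 0.0)
    ub_n = np.maximum(-system.lb, 0.0)
    res = linprog(
        np.ones(2 * n),
        A_eq=A_eq,
        b_eq=np.zeros(system.S.shape[0]),
        bounds=list(zip(np.concatenate([lb_p, lb_n]), np.concatenate([ub_p, ub_n]))),
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"pFBA LP failed with status {res.status}")
    v = res.x[:n] - res.x[n:]
    return dict(zip(system.reaction_ids, v.tolist()))


def nutrient_requirements(
    model: MetabolicModel, biomass_flux: float = 1.0
) -> RequirementProfile:
    """Exchange-flux profile at a fixed biomass flux.

    The biomass reaction is pinned to ``biomass_flux`` (an infeasible pin
    raises, it never silently returns zeros); the reported fluxes are the
    parsimonious solution and each exchange additionally carries its
    flux-variability (min, max) range at that growth."""
    biomass = _biomass_reaction(model)
    achievable = max_growth(model)
    if achievable + FLUX_TOL < biomass_flux:
        raise ValueError(
            f"infeasible at requested growth: max growth {achievable:.6g} < "
            f"{biomass_flux}"
        )
    pinned = model.copy()
    pinned.reactions[biomass.id].lower_bound = biomass_flux
    pinned.reactions[biomass.id].upper_bound = biomass_flux
    fluxes = parsimonious_fluxes(pinned)

    profile = RequirementProfile(
        variety=biomass.id.removeprefix("BIOMASS_"), biomass_flux=biomass_flux
    )
    for rxn in pinned.reactions_of_kind("exchange"):
        if "temporary_sink" in rxn.tags:
            continue
        lo, hi = _flux_range(pinned, rxn.id)
        profile.exchange_fluxes[rxn.id] = fluxes[rxn.id]
        profile.fva[rxn.id] = (lo, hi)
        profile.bounds[rxn.id] = (rxn.lower_bound, rxn.upper_bound)
        cls = sorted(rxn.tags - {"biomass"})
        profile.classes[rxn.id] = cls[0] if cls else ""
    return profile


def profile_to_rows(profile: RequirementProfile) -> list[dict]:
    """Flatten a RequirementProfile into rows: nutrient, flux, fva_min,
    fva_max, class, bounds."""
    rows = []
    for rid in sorted(profile.exchange_fluxes):
        lo, hi = profile.fva[rid]
        blo, bhi = profile.bounds[rid]
        rows.append({
            "nutrient": rid.removeprefix("EX_"),
            "flux": profile.exchange_fluxes[rid],
            "fva_min": lo,
            "fva_max": hi,
            "class": profile.classes.get(rid, ""),
            "bounds": f"({blo:g}, {bhi:g})",
        })
    return rows
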