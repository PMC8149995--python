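"""Synthetic KEGG-like universes with planted ground truth.

The generator emits the same TSV dialects that :mod:`gsmforge.universe_io`
reads, structured so that every pipeline stage has a known right answer:

* ``n_pathways`` linear pathway modules (isomerization chains from a feed
  compound to a biomass precursor), mass-balanced by construction;
* withheld *gap* reactions (present in the universe, unannotated, so absent
  from the draft) that split modules into two weakly connected components;
* planted unbalanced reactions with known minimal filler fixes;
* chiral D-/alpha- duplicate pairs, generic class-compound reactions,
  total/step reaction chains and symbolic-coefficient reactions, all
  removable without disconnecting anything;
* synthesis lesions (missing terminal reactions, one wrong-direction
  reaction) with known minimal repair sets;
* an energy subsystem (a fed sugar phosphorylating ADP at 30 ATP per
  molecule) so biomass maintenance is a real, bounded cost;
* per-variety composition tables whose bottleneck precursor fixes the
  achievable growth rate analytically (uptake bound / biomass coefficient).

Chemistry is token-level (synthetic formulas over a small element alphabet,
including a pseudo-element for the adenosine moiety): the logic under test
is balancing and connectivity, not biochemistry.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from gsmforge.boundary_biomass import DEFAULT_MAINTENANCE
from gsmforge.gapfill import DEFAULT_CURRENCY

ATOMIC_MASS = {
    "C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "P": 30.974,
    "X": 100.0, "Mg": 24.305, "Zn": 65.38,
}

WATER, ATP, ADP, PHOSPHATE, PROTON, ELECTRON = (
    "C00001", "C00002", "C00008", "C00009", "C00080", "C05359",
)
METHANE, ETHYLENE = "C01438", "C06547"
ENERGY_SUGAR, ENERGY_WASTE = "C70001", "C70002"
ATP_PER_SUGAR = 30

FEED_UPTAKE = 5.0    # mmol gDW^-1 h^-1, feed-nutrient exchange lower bound
TRACE_UPTAKE = 1.0


@dataclass
class VarietyProfile:
    name: str
    scale: float       # multiplies all measured contents
    moisture: float    # water mass fraction of the fresh sample


#: Five variety profiles emulating a five-variety commercial sampling
#: design; scales are chosen so the planted growth rates span roughly
#: 2.3-3.4 h^-1 with a single fastest-growing variety.
DEFAULT_PROFILES = [
    VarietyProfile("Lutai", 1.078, 0.75),
    VarietyProfile("Riyekuai", 0.733, 0.74),
    VarietyProfile("Kehai", 0.884, 0.76),
    VarietyProfile("Guangtai", 0.823, 0.75),
    VarietyProfile("Puruiying", 1.064, 0.75),
]


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_pathways: int = 20
    reactions_per_pathway: int = 6
    n_compounds: int = 0  # minimum compound count (inert padding)
    planted_gaps: int = 5
    planted_unbalanced: int = 3
    planted_chiral_pairs: int = 2
    planted_generic: int = 2
    planted_step_chains: int = 2
    planted_symbolic: int = 1
    planted_incomplete: int = 1
    planted_single_lesions: int = 1
    planted_triple_lesions: int = 1
    planted_reversals: int = 1
    annotation_coverage: float = 1.0
    content_jitter: float = 0.04  # relative measurement noise on contents
    maintenance_coefficient: float = DEFAULT_MAINTENANCE
    variety_profiles: list[VarietyProfile] = field(
        default_factory=lambda: list(DEFAULT_PROFILES)
    )

    def validate(self) -> None:
        counts = [
            self.n_pathways, self.reactions_per_pathway, self.n_compounds,
            self.planted_gaps, self.planted_unbalanced, self.planted_chiral_pairs,
            self.planted_generic, self.planted_step_chains,
            self.planted_single_lesions, self.planted_triple_lesions,
            self.planted_reversals,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0 < self.annotation_coverage <= 1:
            raise ValueError("annotation_coverage must be in (0, 1]")
        needed = (
            self.planted_gaps + self.planted_single_lesions
            + self.planted_triple_lesions + self.planted_reversals
        )
        if needed > self.n_pathways:
            raise ValueError(
                f"{needed} gap/lesion modules requested but only "
                f"{self.n_pathways} pathways configured"
            )
        if self.reactions_per_pathway < 5:
            raise ValueError("need >= 5 reactions per pathway for planted lesions")

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        profiles = data.pop("variety_profiles", None)
        cfg = cls(**data)
        if profiles is not None:
            cfg.variety_profiles = [
                VarietyProfile(**p) if isinstance(p, dict) else VarietyProfile(*p)
                for p in profiles
            ]
        return cfg


@dataclass
class GroundTruth:
    """Planted answers, recorded while the universe is constructed."""

    gap_reactions: list[tuple[str, str]] = field(default_factory=list)  # (rid, scale)
    unbalanced_fixes: dict[str, dict[str, int]] = field(default_factory=dict)
    chiral_alias_map: dict[str, str] = field(default_factory=dict)
    chiral_modified: list[str] = field(default_factory=list)
    removable: dict[str, list[str]] = field(default_factory=lambda: {
        "step": [], "generic": [], "incomplete_or_symbolic": [], "chiral_duplicate": [],
    })
    blocked_precursors: list[dict] = field(default_factory=list)
    growth: dict[str, float] = field(default_factory=dict)
    wcc_before: int = 0
    wcc_after: int = 0
    draft_counts: dict[str, int] = field(default_factory=dict)
    supplemented_count: int = 0
    boundary_pairs: int = 0
    precursors: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, data: dict) -> "GroundTruth":
        gt = cls(**data)
        gt.gap_reactions = [tuple(x) for x in gt.gap_reactions]
        return gt


def _formula_str(formula: dict[str, int]) -> str:
    return "".join(f"{el}{n if n != 1 else ''}" for el, n in sorted(formula.items()))


def _mass(formula: dict[str, int]) -> float:
    return sum(ATOMIC_MASS[el] * n for el, n in formula.items())


class _World:
    """Deterministic construction of the whole synthetic study."""

    def __init__(self, config: GeneratorConfig):
        config.validate()
        self.config = config
        self.rng = random.Random(config.seed)
        self.truth = GroundTruth()
        # compound id -> (name, formula dict | None, charge, aliases)
        self.compounds: dict[str, tuple[str, Optional[dict], int, set[str]]] = {}
        # reaction id -> dict(equation, direction, ec, main, pathways, subsystem)
        self.reactions: dict[str, dict] = {}
        self.pathway_subsystem: dict[str, str] = {}
        self.gene_rows: list[tuple[str, str]] = []
        self.generic_compounds: list[str] = []
        self.alias_policy: dict[str, str] = {}
        self.nutrient_classes: dict[str, list[str]] = {}
        self.molar_masses: dict[str, tuple[str, float]] = {}
        self.compositions: list[tuple[str, str, str, str]] = []  # variety, cid, content, unit
        self._gene_counter = 0
        self._annotated: set[str] = set()
        self._withheld: set[str] = set()
        self._build()

    # -- helpers -----------------------------------------------------------

    def _add_compound(self, cid, name, formula, charge=0, aliases=()):
        self.compounds[cid] = (name, formula, charge, set(aliases))

    def _add_reaction(self, rid, equation, direction="forward", ec="",
                      pathways=(), subsystem="", annotate=True, genes=1):
        self.reactions[rid] = {
            "equation": equation, "direction": direction, "ec": ec,
            "pathways": list(pathways), "subsystem": subsystem,
        }
        if annotate and ec:
            for _ in range(genes):
                self._gene_counter += 1
                self.gene_rows.append((f"svn:{100000 + self._gene_counter}", ec))
            self._annotated.add(rid)
        elif not annotate:
            self._withheld.add(rid)

    # -- construction ------------------------------------------------------

    def _build(self):
        cfg = self.config
        self._build_currency()
        self._build_energy()
        self._assign_roles()
        self._build_modules()
        self._build_minerals()
        self._build_classes()
        self._build_compositions()
        self._pad_compounds()
        self._apply_coverage()
        self._bookkeeping()

    def _build_currency(self):
        self._add_compound(WATER, "water", {"H": 2, "O": 1})
        self._add_compound(ATP, "ATP analog", {"X": 1, "P": 3, "O": 13})
        self._add_compound(ADP, "ADP analog", {"X": 1, "P": 2, "O": 10})
        self._add_compound(PHOSPHATE, "phosphate", {"P": 1, "O": 4, "H": 1})
        self._add_compound(PROTON, "proton", {"H": 1})
        self._add_compound(ELECTRON, "electron", {}, charge=-1)
        self._add_compound(METHANE, "methane", {"C": 1, "H": 4})
        self._add_compound(ETHYLENE, "ethylene", {"C": 2, "H": 4})

    def _build_energy(self):
        formula = {"C": 6, "H": 12, "O": 6}
        self._add_compound(ENERGY_SUGAR, "energy sugar", dict(formula))
        self._add_compound(ENERGY_WASTE, "spent sugar", dict(formula))
        self.molar_masses[ENERGY_SUGAR] = ("energy sugar", round(_mass(formula), 3))
        self.pathway_subsystem["pw900"] = "ss0"
        n = ATP_PER_SUGAR
        equation = (
            f"{ENERGY_SUGAR} + {n} {ADP} + {n} {PHOSPHATE} + {n} {PROTON} => "
            f"{n} {ATP} + {n} {WATER} + {ENERGY_WASTE}"
        )
        self._add_reaction("R70001", equation, ec="9.9.9.1", pathways=["pw900"])

    def _assign_roles(self):
        cfg = self.config
        order = iter(range(cfg.n_pathways))

        def take(n):
            return [next(order) for _ in range(n)]

        self.gap_modules = take(cfg.planted_gaps)
        self.single_lesion_modules = take(cfg.planted_single_lesions)
        self.triple_lesion_modules = take(cfg.planted_triple_lesions)
        self.reversal_modules = take(cfg.planted_reversals)
        remaining = list(order)
        # redundancy plants ride along inside ordinary modules (cyclically)
        pool = remaining or list(range(cfg.n_pathways))
        self.step_modules = [pool[i % len(pool)] for i in range(cfg.planted_step_chains)]
        self.generic_modules = [pool[(i + 7) % len(pool)] for i in range(cfg.planted_generic)]
        self.chiral_modules = [pool[(i + 3) % len(pool)] for i in range(cfg.planted_chiral_pairs)]
        self.unbalanced_modules = [
            pool[(i + 5) % len(pool)] for i in range(cfg.planted_unbalanced)
        ]
        self.misc_module = pool[-1]

    def _module_formula(self, m: int) -> dict[str, int]:
        return {"C": 3 + m % 4, "H": 6 + 2 * (m % 3), "O": 2 + m % 3}

    def _cid(self, m: int, k: int) -> str:
        return f"C1{m:02d}{k:02d}"

    def _rid(self, m: int, k: int) -> str:
        return f"R1{m:02d}{k:02d}"

    def _build_modules(self):
        cfg = self.config
        L = cfg.reactions_per_pathway
        unbalanced_variants = ["water", "proton", "electron"]

        for m in range(cfg.n_pathways):
            pathway = f"pw{m:03d}"
            self.pathway_subsystem[pathway] = f"ss{m % 4}"
            base = self._module_formula(m)

            variant = None
            if m in self.unbalanced_modules:
                variant = unbalanced_variants[self.unbalanced_modules.index(m) % 3]

            # compounds k = 0..L; the variant perturbs k >= 2 so that exactly
            # the k=1 -> k=2 reaction is unbalanced
            for k in range(L + 1):
                formula, charge = dict(base), 0
                if variant is not None and k >= 2:
                    if variant == "water":
                        formula["H"] -= 2
                        formula["O"] -= 1
                    elif variant == "proton":
                        formula["H"] -= 1
                    else:  # electron: one positive charge short on the right
                        charge = 1
                self._add_compound(self._cid(m, k), f"met {m}.{k}", formula, charge)

            gap_k = L // 2
            trimmed = 0
            if m in self.single_lesion_modules:
                trimmed = 1
            elif m in self.triple_lesion_modules:
                trimmed = 3

            for k in range(L):
                rid = self._rid(m, k)
                a, b = self._cid(m, k), self._cid(m, k + 1)
                ec = f"{(m % 6) + 1}.{k + 1}.{m + 1}.1"
                kwargs = dict(ec=ec, pathways=[pathway])
                equation, direction = f"{a} => {b}", "forward"

                if m in self.gap_modules and k == gap_k:
                    gap_index = self.gap_modules.index(m)
                    scale = "pathway" if gap_index % 2 == 0 else "global"
                    if scale == "global":
                        kwargs["pathways"] = []
                    self._add_reaction(rid, equation, direction, annotate=False, **kwargs)
                    self.truth.gap_reactions.append((rid, scale))
                    continue
                if trimmed and k >= L - trimmed:
                    self._add_reaction(rid, equation, direction, annotate=False, **kwargs)
                    continue
                if m in self.reversal_modules and k == L - 1:
                    equation = f"{b} => {a}"  # wrong direction planted
                    self._add_reaction(rid, equation, direction, **kwargs)
                    self.truth.blocked_precursors.append({
                        "compound": self._cid(m, L),
                        "repair": [["reverse", rid]],
                    })
                    continue
                genes = 2 if (m == 0 and k == 0) else 1
                self._add_reaction(rid, equation, direction, genes=genes, **kwargs)
                if m == 1 and k == 0:  # an isozyme through a second EC -> OR
                    extra_ec = f"{(m % 6) + 1}.{k + 1}.{m + 1}.99"
                    self.reactions[rid]["ec"] += f";{extra_ec}"
                    self._gene_counter += 1
                    self.gene_rows.append((f"svn:{100000 + self._gene_counter}", extra_ec))

            if m in self.single_lesion_modules:
                self.truth.blocked_precursors.append({
                    "compound": self._cid(m, L),
                    "repair": [["add", self._rid(m, L - 1)]],
                })
            if m in self.triple_lesion_modules:
                self.truth.blocked_precursors.append({
                    "compound": self._cid(m, L),
                    "repair": [["add", self._rid(m, k)] for k in (L - 3, L - 2, L - 1)],
                })

            if m in self.unbalanced_modules:
                rid = self._rid(m, 1)
                fix = {"water": {WATER: 1}, "proton": {PROTON: 1},
                       "electron": {ELECTRON: 1}}[variant]
                self.truth.unbalanced_fixes[rid] = fix

            self.truth.precursors.append(self._cid(m, L))

        self._build_steps()
        self._build_generic()
        self._build_chiral()
        self._build_misc()

    def _build_steps(self):
        for i, m in enumerate(self.step_modules):
            base = self._module_formula(m)
            inter = f"C40{i:03d}"
            self._add_compound(inter, f"step intermediate {i}", dict(base))
            a, b = self._cid(m, 0), self._cid(m, 1)
            pathway = f"pw{m:03d}"
            r1, r2 = f"R40{i:03d}1", f"R40{i:03d}2"
            self._add_reaction(r1, f"{a} => {inter}", ec=f"7.1.{i + 1}.1",
                               pathways=[pathway])
            self._add_reaction(r2, f"{inter} => {b}", ec=f"7.2.{i + 1}.1",
                               pathways=[pathway])
            self.truth.removable["step"] += [r1, r2]

    def _build_generic(self):
        for i, m in enumerate(self.generic_modules):
            base = self._module_formula(m)
            gid = f"C6{i:03d}0"
            self._add_compound(gid, f"a generic class compound {i}", dict(base))
            self.generic_compounds.append(gid)
            rid = f"R6{i:03d}0"
            self._add_reaction(rid, f"{self._cid(m, 1)} => {gid}",
                               ec=f"8.1.{i + 1}.1", pathways=[f"pw{m:03d}"])
            self.truth.removable["generic"].append(rid)

    def _build_chiral(self):
        for i, m in enumerate(self.chiral_modules):
            base = self._module_formula(m)
            d_id, a_id = f"C5{i:03d}1", f"C5{i:03d}2"
            self._add_compound(d_id, f"D-met {i}", dict(base), aliases={a_id})
            self._add_compound(a_id, f"alpha-met {i}", dict(base))
            self.alias_policy[d_id] = a_id
            r1, r2 = f"R5{i:03d}1", f"R5{i:03d}2"
            src = self._cid(m, 1)
            pathway = f"pw{m:03d}"
            self._add_reaction(r1, f"{src} => {d_id}", ec=f"5.1.{i + 1}.1",
                               pathways=[pathway])
            self._add_reaction(r2, f"{src} => {a_id}", ec=f"5.2.{i + 1}.1",
                               pathways=[pathway])
            self.truth.chiral_alias_map[d_id] = a_id
            self.truth.chiral_modified.append(r1)
            self.truth.removable["chiral_duplicate"].append(r2)

    def _build_misc(self):
        m = self.misc_module
        pathway = f"pw{m:03d}"
        a, b = self._cid(m, 0), self._cid(m, 1)
        for i in range(self.config.planted_symbolic):
            rid = f"R710{i:02d}"
            self._add_reaction(rid, f"n {a} => n {b}", ec=f"6.1.{i + 1}.1",
                               pathways=[pathway])
            self.truth.removable["incomplete_or_symbolic"].append(rid)
        for i in range(self.config.planted_incomplete):
            rid = f"R711{i:02d}"
            self._add_reaction(rid, f"{a} => ", ec=f"6.2.{i + 1}.1",
                               pathways=[pathway])
            self.truth.removable["incomplete_or_symbolic"].append(rid)

    def _build_minerals(self):
        for i, el in enumerate(("Mg", "Zn")):
            cid = f"C8000{i + 1}"
            self._add_compound(cid, f"mineral {el}", {el: 1})
            self.molar_masses[cid] = (f"mineral {el}", ATOMIC_MASS[el])

    def _build_classes(self):
        cfg = self.config
        feeds = [self._cid(m, 0) for m in range(cfg.n_pathways)]
        self.nutrient_classes = {
            "amino_acids": feeds,
            "saccharides": [ENERGY_SUGAR],
            "minerals": ["C80001", "C80002"],
            # secretion-only outlets for the spent energy carrier and the
            # currency byproducts of maintenance and balancing fillers
            "cofactors": [ENERGY_WASTE, WATER, PROTON, ELECTRON],
        }
        self.truth.boundary_pairs = sum(len(v) for v in self.nutrient_classes.values())

    def _build_compositions(self):
        cfg = self.config
        L = cfg.reactions_per_pathway
        # target dry-basis coefficients (mmol/gDW): module 0 is the designed
        # bottleneck, the rest sit well below it
        targets = [2.0] + [
            round(self.rng.uniform(0.4, 1.4), 3) for _ in range(cfg.n_pathways - 1)
        ]
        for m in range(cfg.n_pathways):
            cid = self._cid(m, L)
            name, formula, _, _ = self.compounds[cid]
            self.molar_masses[cid] = (name, round(_mass(formula), 3))

        mineral_base = {
            cid: self.rng.uniform(80.0, 300.0) for cid in ("C80001", "C80002")
        }
        energy_cap = FEED_UPTAKE * ATP_PER_SUGAR / cfg.maintenance_coefficient
        for profile in cfg.variety_profiles:
            caps = [energy_cap]
            for m in range(cfg.n_pathways):
                cid = self._cid(m, L)
                mw = self.molar_masses[cid][1]
                jitter = 1.0 + cfg.content_jitter * (self.rng.random() - 0.5)
                coeff = targets[m] * profile.scale * jitter
                content = coeff * mw * (1.0 - profile.moisture) / 10.0
                text = f"{content:.4f}"
                self.compositions.append((profile.name, cid, text, "g/100g"))
                realized = float(text) * 10.0 / mw / (1.0 - profile.moisture)
                caps.append(FEED_UPTAKE / realized)
            for cid in ("C80001", "C80002"):
                mw = self.molar_masses[cid][1]
                jitter = 1.0 + cfg.content_jitter * (self.rng.random() - 0.5)
                content = mineral_base[cid] * profile.scale * jitter
                text = f"{content:.2f}"
                self.compositions.append((profile.name, cid, text, "mg/kg"))
                realized = float(text) / mw / 1000.0 / (1.0 - profile.moisture)
                caps.append(TRACE_UPTAKE / realized)
            self.compositions.append(
                (profile.name, "MOISTURE", f"{profile.moisture:.2f}", "fraction")
            )
            self.truth.growth[profile.name] = min(caps)

    def _pad_compounds(self):
        i = 0
        while len(self.compounds) < self.config.n_compounds:
            self._add_compound(f"C9{i:04d}", f"inert {i}", {"C": 1, "H": 4})
            i += 1

    def _apply_coverage(self):
        cov = self.config.annotation_coverage
        if cov >= 1.0:
            return
        eligible = sorted(self._annotated)
        keep = round(cov * len(eligible))
        kept = set(self.rng.sample(eligible, keep))
        dropped_ecs = set()
        for rid in eligible:
            if rid not in kept:
                dropped_ecs.update(self.reactions[rid]["ec"].split(";"))
                self._withheld.add(rid)
        self._annotated = kept
        kept_ecs = {
            ec for rid in kept for ec in self.reactions[rid]["ec"].split(";")
        }
        self.gene_rows = [
            (g, ec) for g, ec in self.gene_rows
            if ec in kept_ecs or ec not in dropped_ecs
        ]

    def _bookkeeping(self):
        cfg = self.config
        truth = self.truth
        # WCC accounting: one component per module plus the energy
        # subsystem; every withheld gap splits its module in two
        truth.wcc_after = cfg.n_pathways + 1
        truth.wcc_before = truth.wcc_after + len(truth.gap_reactions)

        genes = {g for g, _ in self.gene_rows}
        ecs = {ec for rid in self._annotated
               for ec in self.reactions[rid]["ec"].split(";") if ec}
        pathways = {p for rid in self._annotated
                    for p in self.reactions[rid]["pathways"]}
        truth.draft_counts = {
            "genes": len(genes),
            "enzymes": len(ecs),
            "reactions": len(self._annotated),
            "pathways": len(pathways),
            # the emitted tables leave the subsystem column empty; it is
            # only filled during metadata supplementation
            "subsystems": 0,
        }
        removed = {rid for ids in truth.removable.values() for rid in ids}
        truth.supplemented_count = len(self._annotated - removed)

    # -- emission ----------------------------------------------------------

    def write(self, out_dir: Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def table(name, header, rows):
            path = out_dir / name
            with open(path, "w") as fh:
                fh.write("\t".join(header) + "\n")
                for row in rows:
                    fh.write("\t".join(str(c) for c in row) + "\n")
            paths[name.removesuffix(".tsv")] = path
            return path

        table("compounds.tsv", ["id", "name", "formula", "charge", "aliases"], [
            (cid, name,
             _formula_str(formula) if formula else ("-" if formula == {} else ""),
             charge, ";".join(sorted(aliases)))
            for cid, (name, formula, charge, aliases) in sorted(self.compounds.items())
        ])
        table("reactions.tsv",
              ["id", "equation", "direction", "ec_numbers", "main_reaction_id",
               "pathways", "subsystem"],
              [(rid, r["equation"], r["direction"], r["ec"], "",
                ";".join(r["pathways"]), r["subsystem"])
               for rid, r in sorted(self.reactions.items())])
        table("pathways.tsv", ["pathway_id", "subsystem"],
              sorted(self.pathway_subsystem.items()))
        table("enzymes.tsv", ["ec", "reaction_id"], sorted(
            (ec, rid) for rid, r in self.reactions.items()
            for ec in r["ec"].split(";") if ec
        ))
        table("genes.tsv", ["gene_id", "ec"], self.gene_rows)
        table("compositions.tsv", ["variety", "compound_id", "content", "unit"],
              self.compositions)
        table("alias_policy.tsv", ["alias_id", "canonical_id"],
              sorted(self.alias_policy.items()))
        table("generic_compounds.tsv", ["compound_id"],
              [(c,) for c in sorted(self.generic_compounds)])
        table("currency.tsv", ["compound_id"], [(c,) for c in sorted(DEFAULT_CURRENCY)])
        table("nutrient_classes.tsv", ["class", "compound_id"], sorted(
            (cls, cid) for cls, cids in self.nutrient_classes.items() for cid in cids
        ))
        table("molar_masses.tsv", ["compound_id", "name", "molar_mass"], sorted(
            (cid, name, mass) for cid, (name, mass) in self.molar_masses.items()
        ))

        gt_path = out_dir / "ground_truth.json"
        with open(gt_path, "w") as fh:
            json.dump(self.truth.to_json(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        paths["ground_truth"] = gt_path
        return paths


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def generate_universe(
    config: GeneratorConfig, out_dir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Emit the full synthetic study (universe tables, annotations,
    compositions, policy files) into *out_dir* and return the paths plus
    the planted ground truth."""
    world = _World(config)
    return world.write(Path(out_dir)), world.truth


def generate_annotations(config: GeneratorConfig, out_dir: str | Path) -> Path:
    """Emit only the gene annotation table for the configured universe."""
    paths, _ = generate_universe(config, out_dir)
    return paths["genes"]


def generate_compositions(
    config: GeneratorConfig, out_dir: str | Path
) -> tuple[Path, dict[str, float]]:
    """Emit only the per-variety composition table; returns its path and
    the analytically known achievable growth rate per variety."""
    paths, truth = generate_universe(config, out_dir)
    return paths["compositions"], truth.growth


def load_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_json(json.load(fh))
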