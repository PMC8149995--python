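# Methods

## The model

A metabolic network is held as a set of reactions over compartmentalized
metabolites (cytosol `c`, extracellular `e`), each with a net stoichiometry
(negative coefficients = substrates), flux bounds in mmol gDW⁻¹ h⁻¹, a kind
(`metabolic`, `transport`, `exchange`, `biomass`) and an optional GPR rule.
Simulation is standard flux balance analysis: at steady state `S·v = 0`
with `lb ≤ v ≤ ub`, maximize the objective reaction's flux. Growth rate is
the flux of the biomass pseudo-reaction (h⁻¹); nutrient uptake is a
negative exchange flux.

### Assumptions

- Two compartments suffice; all enzymatic chemistry is cytosolic, boundary
  crossing is explicit transport. Organelle-level localization is not
  modeled.
- GPR semantics: genes reached through the *same* EC number of a reaction
  are treated as subunits of one enzyme (AND); genes reached through
  *different* ECs are alternative catalysts (OR). Isozyme-vs-subunit
  evidence is not available in gene→EC tables, so this convention is
  applied uniformly. GPRs are stored and serialized but not enforced in
  FBA (no knockout simulation).
- The biomass reaction drains measured precursors in their measured
  proportions and cycles maintenance cofactors; its product is a biomass
  pseudo-species. The species lives in `e` and is drained by an ordinary
  exchange, so the structural invariant "an exchange touches exactly one
  extracellular species" holds for every exchange in the model.

## Tunable parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| reversible / irreversible bounds | (−1000, 1000) / (0, 1000) | mmol gDW⁻¹ h⁻¹ | effectively unbounded internal fluxes |
| transport bounds | (−1000, 1000) | 〃 | free bidirectional carriage |
| feed-nutrient exchange | (−5, 1000) | 〃 | uptake capped at the feeding-regime rate |
| trace-element exchange | (−1, 1000) | 〃 | minerals are scarcer in feed |
| synthesizable exchange | (0, 1000) | 〃 | no uptake of what the cell can make |
| maintenance coefficient | 29.8303 | mmol/gDW | energy maintenance borrowed from the closest animal model with measured values; configurable |
| NADPH maintenance | off | — | methods-level cofactor lists omit it; a switch adds an NADPH→NADP⁺ couple at the same coefficient |
| balancing fillers | H₂O, H⁺, e⁻, CH₄, C₂H₄ | — | small species that close element/charge gaps; order is the tie-break preference |
| filler coefficient cap | ±10 | — | bounded search; larger fills indicate a mis-parsed equation |
| currency metabolites | H₂O, H⁺, ATP, ADP, Pᵢ, NAD(P)(H), CO₂, O₂, e⁻ | — | excluded from connectivity, else the WCC partition collapses to one component |
| repair search | ≤ 3 edits, ≤ 20 candidates | — | minimal-repair sets beyond three edits are rarely interpretable |
| requirement growth pin | 1 | h⁻¹ | requirements are read per gram dry weight produced per hour |

## Numerical choices

- **LP solving.** HiGHS through `scipy.optimize.linprog`, deterministic
  settings; feasibility tolerance 10⁻⁹, value comparisons at 10⁻⁶,
  steady-state residual asserted ≤ 10⁻⁸ for every optimal solution.
- **Equation balancing** is an integer program: minimize total absolute
  filler count subject to exact element and charge closure, coefficients
  in [−10, 10]. A tiny order-dependent weight (10⁻⁶ per list position)
  makes ties resolve toward earlier fillers deterministically. No solution
  → the reaction is flagged unbalanceable and left untouched.
- **Exact arithmetic upstream of the LP.** Reference stoichiometries are
  rational (`fractions.Fraction`); coefficients become floats only when a
  network is converted to a bounded model.
- **Alternate optima.** FBA optima at fixed growth are degenerate, so
  requirement profiles report the parsimonious solution (minimum Σ|v| via
  a split-variable LP) together with per-exchange FVA ranges, rather than
  one arbitrary vertex. Individual degenerate flux values from any other
  solver are expected to differ; bound compliance and the FVA envelope are
  the reproducible statements.
- **Step-reaction collapse** handles the pairwise case only: two reactions
  whose shared intermediate occurs nowhere else and cancels exactly, with
  an existing total reaction equal to their sum. Longer chains are left
  alone.
- **Gap filling** is greedy and deterministic: candidates ranked by
  (components merged desc, reaction id asc); pathway scale requires the
  candidate to share a pathway with at least two of the components it
  touches. Each accepted candidate strictly reduces the component count,
  so termination is immediate.
- **Repair search.** Candidate edits are reference-reaction additions
  within three shared-metabolite hops of the model plus direction
  reversals of irreversible reactions. Candidates that cannot carry flux
  toward the target in a fully relaxed super-model (checked by FVA at a
  pinned synthesis flux) are pruned; the survivors are searched
  breadth-first by edit-set size, so the first hit is minimal within the
  pruned pool. The hop expansion is needed because a multi-reaction lesion
  leaves its interior metabolites entirely outside the model.
- **Display rounding** is half-up to two decimals, matching requirement
  tables; internal values keep full precision.

## The synthetic study

The generator emulates the study design end to end: ~20 linear pathway
modules (feed compound → isomerization chain → biomass precursor), an
energy subsystem (one fed sugar phosphorylates 30 ADP per molecule, so
maintenance is a real bounded cost), two trace minerals, and five variety
composition profiles whose contents are a common per-variety scale times a
small measurement jitter. Everything is mass-balanced by construction
except the planted defects, and every defect's correct resolution is
recorded: withheld gap reactions (each splits one module into two WCCs),
unbalanced equations with known minimal filler fixes, chiral D-/α-
duplicate pairs, shadowed step chains, generic-compound reactions,
symbolic-coefficient and incomplete reactions, one-/three-reaction
synthesis lesions and one wrong-direction reaction.

The achievable growth rate per variety is known in closed form: with each
precursor fed through its own chain at uptake ≤ 5 and ATP demand
29.8303·g covered by the sugar at 30 ATP each, the maximum growth is
`min(min_i 5/c_i, 5·30/29.8303, min_m 1/c_m)` over precursor coefficients
`c_i` and mineral coefficients `c_m`. Default profiles put the bottleneck
precursor at dry-basis coefficients that span growth ≈ 2.3–3.4 h⁻¹ with a
single fastest variety, mirroring the magnitudes a real five-variety
sampling produces.

What passing on synthetic data does **not** show: real biochemistry.
Chemistry is token-level (small synthetic formulas, a pseudo-element for
the adenosine moiety, neutral protons), chains are linear with no
branching or shared intermediates, and compositions are perturbations of
one base profile. Real KEGG snapshots bring multi-pathway reactions,
promiscuous enzymes, protonation states and far denser connectivity;
absolute count-style results are snapshot-dependent and are not
reproduction targets.

## Design choices where the design was open

- D-form → α-form chiral standardization is data-driven (an alias-policy
  table shipped with a glucose-family default) rather than hard-coded,
  since the α preference is justified compound by compound.
- Generic reactions are detected by membership of a curated generic-
  compound list applied at parse time, giving "reactants are a class of
  substances" an operational test.
- Incomplete reactions are those with an empty side or full cancellation
  at parse time; symbolic coefficients (`m`/`n`) are flagged, not
  rejected, so redundancy removal can account for them.
- Gap reactions enter the network without gene association and tagged as
  hypothesized; repairs are tagged likewise.
- Model JSON (versioned schema) is the lossless interchange format; SBML
  L3+fbc export carries bounds, objective, gene associations and notes,
  and round-trips to within float-printing precision.

## Known limitations

- Nutrient classification for exchange bounds is by explicit class lists;
  an unclassified exchange falls back to feed-nutrient bounds with a
  warning rather than an error.
- The repair search can miss a globally minimal repair that uses only
  candidates pruned as flux-incapable under the relaxed super-model; on
  linear lesions this cannot happen, on densely connected networks it is
  a heuristic.
- Maintenance is a single lumped coefficient; growth-associated and
  non-growth-associated maintenance are not separated.
- No thermodynamic (loopless) constraints; parsimonious flux minimization
  is the only loop suppression.
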