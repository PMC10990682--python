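# Methods

## Scope and model

`commgem` assembles compartmentalized community metabolic models: each
member keeps its own compartments, and a shared `medium` compartment mediates
every inter-member and environmental exchange. The model stays a plain
constraint-based model throughout — steady state `S·V = 0` with box bounds —
so FBA and FVA are ordinary LPs and the written file is standard SBML L3V1 +
FBC v2 readable by any openCOBRA tool.

### Member preparation

Each member model is sanitised to the SBML SId grammar (invalid characters →
`_`, digit-leading ids prefixed with `_`; collisions are errors, not silent
merges), then every compartment, metabolite, reaction and gene id is prefixed
with the member name, so provenance is carried by the namespace itself. Every
boundary reaction (exchange, demand or sink — anything one-sided) is rewritten
as a transport between the member metabolite and a *medium twin* metabolite,
**retaining the original flux bounds verbatim**; a new community boundary
reaction on the twin starts uptake-closed so growth media are opt-in via
`set_medium`. The twin id is the original (unprefixed) metabolite id with its
compartment suffix replaced by `_medium`, which makes by-ID matching across
members that share a namespace automatic. Routing member demand/sink
reactions through the medium like exchanges is a deliberate simplification:
it treats all one-sided reactions uniformly and keeps "boundary" a purely
structural notion.

### Matching

Boundary metabolites are matched in the medium compartment either by string
equality of their twin ids (case-sensitive — SIds are case-sensitive) or by a
user-chosen annotation database. Annotation matching is strict: it only
proceeds if *every* boundary metabolite carries exactly one identifier in the
chosen database; otherwise it stops with an error naming the offender and
suggesting a different database or by-ID matching. Any annotation key present
in the inputs is accepted as a database. On formula/charge conflicts within
a matched group the most-specified formula (most elements) is kept and the
conflict logged and recorded — merging proceeds, because conflicting
annotations in automatically generated models are common and rarely fatal.

### The bound-free reformulation

Fluxes are dry-mass-normalised, so member *i*'s flux on the community scale
is `V = f_i·v` and every finite member bound must scale with the mass
fraction `f_i`. Constant SBML flux bounds cannot express that, so bounds are
moved into stoichiometry:

1. every member reaction is split into irreversible parts (forward/reverse,
   or sign-flipped when reverse-only), so each part needs only an upper-bound
   constraint plus possibly a forced-flux constraint;
2. for a part with bound `ub_r`, the fraction reaction `F_i` produces `ub_r`
   units of a dummy metabolite, the part consumes one unit per unit flux and
   a slack sink drains the remainder: `ub_r·f_i − V_r − s = 0, s ≥ 0` ⟹
   `V_r ≤ ub_r·f_i`;
3. for a forced flux `lb_r > 0` the roles reverse: the part produces one
   dummy unit per unit flux, `F_i` consumes `lb_r`, a sink drains the surplus
   ⟹ `V_r ≥ lb_r·f_i`.

The default "unconstrained" magnitude (1000 mmol·gCDW⁻¹·h⁻¹, the COBRA
convention) is transformed like any other bound — a member at fraction `f`
can never exceed `1000·f` on any reaction. Transformed reactions carry only
the structural bounds `(0, 1000)`, which never bind more tightly than their
dummy constraints. A budget metabolite produced at a fixed rate of 1 and
consumed 1:1 by every `F_i` pins `Σ f_i = 1` at steady state. This particular
sink-slack encoding is one of several equivalent ways to express the two
inequalities; the normative property is equivalence with directly scaled
bounds, which the test suite checks against an independently constructed
reference model (bounds literally multiplied by `f_i`) on seeded random
communities.

The original bounds of every member reaction are recoverable exactly from
the dummy registry (`original_bounds`), so the transform is lossless and the
written community model is reusable and re-editable.

### Linearization modes

Community growth is bilinear (μ times `f_i`). Two linearizations are
supported, switchable in place (only bounds and coefficients change; the
reaction set is never rebuilt):

* **fixed abundance** — each `F_i` clamped to `f_i`; each member biomass
  reaction produces a biomass species `X_i`, consumed with coefficient `f_i`
  by the community biomass reaction, so its flux is the community growth rate
  μ with balanced growth `V_bio,i = μ·f_i`. Members at `f_i = 0` are excluded
  from the community biomass (their fluxes are already forced to zero by the
  dummy coupling) and their `X_i` sink stays closed.
* **fixed growth** — `F_i` free in `[0, 1]`; a per-member coupling dummy
  `G_i` is produced by `F_i` with coefficient μ and consumed 1:1 by the
  biomass reaction, with no sink, enforcing `V_bio,i = μ·f_i` exactly.
  μ = 0 is encoded by omitting the `F_i → G_i` coefficient, which forces all
  biomass fluxes to zero. The community biomass coefficients are set to a
  feasibility placeholder (−1 per `X_i`, with the `X_i` sinks opened); the
  quantity of interest in this mode is the fraction-reaction FVA, not the
  community biomass flux.

The machinery metabolites (budget, dummies, `X_i`, `G_i`) live in the medium
compartment, which keeps the community biomass reaction a single well-formed
reaction and avoids inventing pseudo-compartments.

### Analyses

* `max_community_growth(fractions)` — fixed-abundance FBA; infeasibility is
  reported as growth 0 with a warning rather than an exception, matching how
  the number is used in scans.
* `feasible_composition(mu)` — fixed-growth FVA over the fraction reactions,
  returning per-member `[f_min, f_max]`; an infeasible μ yields an explicit
  "no feasible composition" result.
* `potential_exchanges()` — composition left variable (`F_i ∈ [0,1]`,
  budget `Σ f_i = 1`) *and* growth coupling removed (`G_i` decoupled, `X_i`
  sinks opened): one FVA over every member↔medium transport and community
  boundary then bounds the exchange ranges of *every* fixed composition at
  once (the superset property is tested against a brute-force 0.1-step grid
  loop). Roles per (member, metabolite) with member→medium flux positive:
  producer (`max > tol`), consumer (`min < −tol`), both, none; a metabolite
  is cross-fed when some member can produce it and a *different* member can
  consume it. Because growth rates are decoupled, the ranges may include
  interactions infeasible under balanced growth — accepted and flagged in the
  result (`decoupled_growth=True`), not corrected.
* `detect_infeasible_cycles()` — all community boundary reactions closed to
  `(0,0)`, fraction machinery left variable, FVA over all member reactions
  (net of split pairs): any reaction with `|flux| > tol` sustains flux with
  zero environmental exchange, i.e. sits on a thermodynamically infeasible
  loop. Slack sinks and bookkeeping reactions carry bound slack, not matter,
  and are exempt. This closed-boundary FVA criterion is this package's
  operationalization of cycle finding; it detects loops but does not remove
  them (no loopless FVA).

Every analysis snapshots and restores all reaction bounds, stoichiometries
and mode state, so no analysis mutates the community model.

## Numerical choices

* Global tolerance `1e−6` for feasibility, optimality and zero-flux
  classification (`commgem.config.TOLERANCE`).
* LPs are solved with scipy's HiGHS (`scipy.optimize.linprog`); FVA reuses
  one cached constraint matrix per model state and re-solves per objective.
  Net fluxes of split forward/reverse pairs are computed as min/max of the
  linear combination `v_fwd − v_rev`, never by summing separate FVA ranges.
* FVA results are clipped into the reaction's own bounds to absorb solver
  round-off; fraction ranges are clipped into `[0, 1]`.
* Infinite bounds on read are clamped to ±1000 and logged.
* SBML doubles serialise at ~15 significant digits; on load, the model-level
  state annotation (exact JSON) is re-applied, so mode-dependent bounds and
  coefficients are restored at full precision and round-trips compare exactly.
* Formula parsing is Hill-notation only; polymer/R-group formulas make the
  balance verdict `unknown` rather than guessing.
* Mass/charge balance checking warns and records; it never blocks model
  construction (boundary reactions are exempt by definition).

## Fixtures: what they emulate, and what they don't

The packaged toy communities are built so every oracle value is
hand-derivable (biomass stoichiometry is 1:1 in abstract units):

* **chain** — a linear dependency chain (only member 1 has an environmental
  substrate, bound 10); forces strict compositional ordering `f₁ ≥ f₂ ≥ …`
  under balanced growth and gives closed-form optima and composition windows.
* **cycle2** — two members interconverting formate ↔ H₂ + CO₂ in opposite
  directions through the medium, with growth fed separately: a minimal
  thermodynamically infeasible cycle (formate encoded as neutral CH2O2 so
  the conversions are balanced as written).
* **biogas toy** — a three-guild syntrophy on an ethanol + CO₂ medium: a
  fermenter (ethanol → acetate + H₂ or formate), a formate/H₂ methanogen and
  an acetate/H₂ methanogen. It reproduces the interaction *topology* of a
  published ethanol-fed biogas community — cross-feeding via acetate, H₂,
  CO₂ and formate with the fermenter the sole ethanol consumer — at toy
  scale. It is a synthetic stand-in: the real genome-scale models have
  thousands of reactions, realistic biomass compositions, cofactor coupling
  and redundant pathways, none of which exist here.
* **random members** — seeded linear pathways (3–15 reactions, bounds
  uniform in [0.1, 50] rounded to 6 decimals, ~35 % reversible steps, ~15 %
  forced-flux steps at 2 % of the upper bound) driving the equivalence
  property tests; seeds are recorded in the model metadata.

Passing tests on these fixtures demonstrates the *construction and analysis
machinery* — equivalence of the bound-free form, mode switching, matching,
round trips, the superset property, cycle detection — not biological realism.
Uptake kinetics, thermodynamics, regulation and biomass composition are out
of scope, as are MATLAB/YAML input formats, gap-filling, loopless FVA, flux
sampling, and simultaneous (bilinear) optimisation of μ and composition.

## Problem sizes used in validation

The equivalence check runs 20 seeded random communities (2–4 members, ≤ 15
reactions each) at 5 random simplex compositions each; the superset check
uses a 0.1-step abundance grid (11 points for two members, 66 for three).
These sizes keep every documented optimum auditable while exercising all
code paths (reversible splits, forced fluxes, shared medium metabolites,
infeasible compositions).
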