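# commgem

**Compartmentalized community metabolic models with abundance as a model
variable.**

`commgem` builds one standards-compliant community genome-scale metabolic
model (SBML Level 3 + FBC v2) out of single-organism models, and predicts

1. the maximum community growth rate at a given abundance profile,
2. the feasible community compositions at a given growth rate, and
3. all potential exchange metabolites and cross-feeding interactions —
   independent of the abundance profile, with a single flux variability
   analysis (FVA) run.

It is aimed at microbial-ecology and systems-biology workflows (syntrophic
consortia, gut communities, bioreactor communities) where the member models
exist but the community composition is unknown or variable.

## The model

Fluxes in a genome-scale model are normalised to dry mass. In a community,
the flux of member *i* on the community scale is `V = f_i · v`, where `f_i`
is the member's mass fraction (`Σ f_i = 1`) and `v` its cell-specific flux,
so every member flux bound must scale with `f_i`:

```
lb_r · f_i  ≤  V_r  ≤  ub_r · f_i
```

Community growth is bilinear in `f_i` and the growth rate μ. `commgem`
linearizes it in either of two modes — **fixed abundance** (clamp `f`,
optimise μ) and **fixed growth** (clamp μ, leave `f` free) — and makes the
abundance-scaled bounds SBML-representable through a *bound-free* rewrite:
every reaction is split into irreversible parts, and each finite bound
becomes a stoichiometric coefficient on a dummy metabolite coupled to the
member's *fraction reaction* `F_i` (steady-state flux = `f_i`):

* `F_i` produces `ub_r` units of a dummy; reaction *r* consumes 1 per unit
  flux; a slack sink drains the surplus ⟹ `V_r ≤ ub_r · f_i`;
* for forced fluxes, *r* produces a dummy consumed by `F_i` with coefficient
  `lb_r` ⟹ `V_r ≥ lb_r · f_i`.

A budget metabolite produced at fixed rate 1 and consumed by every `F_i`
enforces `Σ f_i = 1`. Balanced growth (`V_bio,i = μ · f_i`) is imposed per
mode through per-member biomass species. Since composition and mode live in
bounds and coefficients only, changing them never re-runs the merge.

For cross-feeding prediction the composition is left variable *and* the
equal-growth constraint is dropped, so one FVA over the member↔medium
transports bounds every fixed composition's exchange ranges at once (the
ranges may include interactions infeasible under balanced growth; the result
flags that decoupled growth was used). Closing every community boundary and
running the same FVA exposes thermodynamically infeasible cycles: internal
loops that carry flux without any net mass input.

## Worked example

```python
from commgem import (build_community_model, prepare_member, set_medium,
                     max_community_growth, feasible_composition,
                     potential_exchanges)
from commgem.fixtures import make_chain_community

chain = make_chain_community()            # A imports S, makes I; B eats I
members = [prepare_member(m, m.id) for m in chain.members]
cm = build_community_model(members)       # bound-free community model
set_medium(cm, {"S_medium": 10.0})        # only S available from outside

print(max_community_growth(cm, {"A": 0.5, "B": 0.5}).objective_value)
print(max_community_growth(cm, {"A": 0.25, "B": 0.75}).objective_value)
print(feasible_composition(cm, 10.0).ranges)
print(potential_exchanges(cm).cross_fed)
```

prints

```
10.0
-0.0
{'A': (0.5, 1.0), 'B': (0.0, 0.5)}
['I_medium']
```

At equal fractions each member can grow at 10 (member A's substrate uptake
bound of 10 · 0.5 feeds B exactly); with B overrepresented (0.75) the
intermediate I produced by A cannot cover B's demand under balanced growth,
so the community cannot grow at all; at μ = 10 the feasible compositions are
exactly `f_A ∈ [0.5, 1]`; and I is the single cross-fed metabolite.

The same workflow is available from the shell:

```
commgem build -m A.xml -m B.xml --medium medium.tsv --out community.xml
commgem exchanges -m A.xml -m B.xml --medium medium.tsv --out exchanges.tsv
```

(subcommands: `build`, `fba`, `composition`, `exchanges`, `cycles`,
`balance`; media and fractions are two-column TSV files).

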