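"""Directly-scaled reference community models (validation path).

For a *fixed* composition the bound-free reformulation must be equivalent to
simply multiplying every member reaction's flux bounds by the member's mass
fraction.  :func:`build_scaled_reference` constructs that directly-bounded
model by brute force — no reversible splitting, no dummy metabolites, no
budget machinery — so it provides an independent check of the transformed
model's solution space.  It is a validation tool, not the production path:
its bounds are literal numbers, so changing the composition means rebuilding.
"""

from __future__ import annotations

from .config import DEFAULT_BOUND
from .errors import CommgemError
from .member_prep import MEDIUM_COMPARTMENT, PreparedMember
from .model_core import MetaboliteSpec, ModelSpec, ReactionSpec

__all__ = ["build_scaled_reference"]


def build_scaled_reference(
    members: list[PreparedMember],
    fractions: dict[str, float],
    medium: dict[str, float] | None = None,
) -> ModelSpec:
    """Merge prepared members with literally scaled bounds (lb·f_i, ub·f_i).

    Shared-medium metabolites are matched by id.  Balanced growth is enforced
    by a community biomass reaction consuming ``f_i`` units of each member's
    biomass species per unit flux.  The model's objective is the community
    biomass reaction (community growth rate μ).
    """
    if set(fractions) != {m.name for m in members}:
        raise CommgemError("fractions must cover exactly the member names")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise CommgemError(f"fractions sum to {total!r}, expected 1")

    out = ModelSpec(
        id="scaled_reference",
        compartments={MEDIUM_COMPARTMENT: "shared growth medium"},
    )
    medium = medium or {}
    seen_medium: set[str] = set()
    biomass_stoich: dict[str, float] = {}
    for member in members:
        f = float(fractions[member.name])
        model = member.model
        twin_ids = set(member.boundary_metabolite_ids)
        own_boundaries = set(member.medium_boundaries.values())
        for cid, cname in model.compartments.items():
            out.compartments.setdefault(cid, cname)
        for met in model.metabolites:
            if met.id in twin_ids:
                if met.id not in seen_medium:
                    seen_medium.add(met.id)
                    out.metabolites.append(met.copy())
            else:
                out.metabolites.append(met.copy())
        for rxn in model.reactions:
            if rxn.id in own_boundaries:
                continue
            scaled = rxn.copy()
            scaled.lower_bound = rxn.lower_bound * f
            scaled.upper_bound = rxn.upper_bound * f
            out.reactions.append(scaled)
        out.genes.extend(model.genes)

        x_id = f"X_{member.name}"
        out.metabolites.append(
            MetaboliteSpec(id=x_id, name=f"biomass of {member.name}",
                           compartment_id=MEDIUM_COMPARTMENT)
        )
        out.reaction(member.biomass_reaction_id).stoichiometry[x_id] = 1.0
        if f > 0:
            biomass_stoich[x_id] = -f

    for met_id in sorted(seen_medium):
        out.reactions.append(
            ReactionSpec(
                id=f"EX_{met_id}",
                name=f"community exchange of {met_id}",
                stoichiometry={met_id: -1.0},
                lower_bound=-float(medium[met_id]) if met_id in medium else 0.0,
                upper_bound=DEFAULT_BOUND,
            )
        )
    out.reactions.append(
        ReactionSpec(
            id="community_biomass",
            name="community biomass",
            stoichiometry=biomass_stoich,
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )
    )
    out.objective = ("community_biomass", "max")
    out.validate()
    return out
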