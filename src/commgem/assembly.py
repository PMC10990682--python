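"""Community model assembly and the bound-free abundance reformulation.

Community growth is bilinear: the community-normalised flux of member *i* is
``V = f_i · v`` where ``f_i`` is the member's dry-mass fraction and ``v`` its
cell-specific flux, so every member flux bound must scale with ``f_i``.  SBML
flux bounds are constants, so instead of writing ``lb_r·f_i ≤ V_r ≤ ub_r·f_i``
as (dynamic) bounds, each bound becomes a stoichiometric coefficient on a
dummy metabolite coupled to the member's *fraction reaction* ``F_i`` (whose
steady-state flux equals ``f_i``):

* upper bound: ``F_i`` produces ``ub_r`` units of a dummy, reaction *r*
  consumes one unit per flux, a slack sink drains the rest — enforcing
  ``V_r ≤ ub_r·f_i``;
* forced lower bound: *r* produces one unit of a dummy, ``F_i`` consumes
  ``lb_r`` units, a slack sink drains the surplus — enforcing
  ``V_r ≥ lb_r·f_i``.

A budget metabolite produced at fixed rate 1 and consumed by every ``F_i``
pins ``Σ f_i = 1``.  Reversible reactions are first split into irreversible
forward/reverse parts so each part needs only single-sided dummies.

Two linearizations make the model an ordinary LP: *fixed abundance* (clamp
every ``F_i`` to ``f_i``; community growth rate μ is optimised) and *fixed
growth* (clamp μ through per-member coupling dummies ``G_i``; the ``F_i``
stay free).  Switching mode or composition only rewrites bounds and
coefficients — the model is never re-merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import DEFAULT_BOUND, TOLERANCE
from .errors import CommgemError, IntegrityError
from .matching import match_by_annotation, match_by_id, merge_into_medium
from .member_prep import MEDIUM_COMPARTMENT, PreparedMember
from .model_core import (
    MetaboliteSpec,
    ModelSpec,
    ReactionSpec,
    sanitize_sid,
)

logger = logging.getLogger("commgem")

__all__ = [
    "MemberRecord",
    "CommunityModel",
    "split_reversible",
    "apply_bound_free_transform",
    "build_community_model",
    "set_medium",
    "set_fixed_abundance",
    "set_fixed_growth",
    "original_bounds",
]

BUDGET_METABOLITE = "fraction_budget"
BUDGET_REACTION = "budget_source"
COMMUNITY_BIOMASS = "community_biomass"


@dataclass
class MemberRecord:
    name: str
    biomass_reaction_id: str
    fraction_reaction_id: str
    biomass_metabolite_id: str
    growth_coupling_metabolite_id: str
    biomass_sink_reaction_id: str


@dataclass
class CommunityModel(ModelSpec):
    """A merged community model; itself a valid :class:`ModelSpec`."""

    members: list[MemberRecord] = field(default_factory=list)
    medium_compartment: str = MEDIUM_COMPARTMENT
    budget_metabolite_id: str = BUDGET_METABOLITE
    budget_reaction_id: str = BUDGET_REACTION
    community_biomass_reaction_id: str = COMMUNITY_BIOMASS
    #: transformed reaction id → [(dummy metabolite id, "ub"|"lb", bound value)]
    dummy_registry: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)
    #: original member reaction id → {"forward": id|None, "reverse": id|None,
    #: "flipped": bool} describing the irreversible decomposition
    split_registry: dict[str, dict] = field(default_factory=dict)
    mode: str = "fixed_abundance"
    mu: float | None = None
    fractions: dict[str, float] | None = None
    #: member name → {medium metabolite id → original transport reaction id}
    member_exchanges: dict[str, dict[str, str]] = field(default_factory=dict)
    #: medium metabolite id → community boundary reaction id
    medium_exchanges: dict[str, str] = field(default_factory=dict)
    #: currently applied medium: medium metabolite id → max uptake flux
    medium: dict[str, float] = field(default_factory=dict)
    #: component id → member name or "community"
    provenance: dict[str, str] = field(default_factory=dict)

    # -- persistence --------------------------------------------------------
    def to_modelspec(self) -> ModelSpec:
        spec = ModelSpec(
            id=self.id,
            name=self.name,
            compartments=dict(self.compartments),
            metabolites=[m.copy() for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            objective=self.objective,
            meta=dict(self.meta),
        )
        spec.meta["community"] = {
            "members": [
                {
                    "name": m.name,
                    "biomass_reaction_id": m.biomass_reaction_id,
                    "fraction_reaction_id": m.fraction_reaction_id,
                    "biomass_metabolite_id": m.biomass_metabolite_id,
                    "growth_coupling_metabolite_id": m.growth_coupling_metabolite_id,
                    "biomass_sink_reaction_id": m.biomass_sink_reaction_id,
                }
                for m in self.members
            ],
            "medium_compartment": self.medium_compartment,
            "budget_metabolite_id": self.budget_metabolite_id,
            "budget_reaction_id": self.budget_reaction_id,
            "community_biomass_reaction_id": self.community_biomass_reaction_id,
            "dummy_registry": {
                rid: [[d, kind, value] for d, kind, value in entries]
                for rid, entries in self.dummy_registry.items()
            },
            "split_registry": self.split_registry,
            "mode": self.mode,
            "mu": self.mu,
            "fractions": self.fractions,
            "member_exchanges": self.member_exchanges,
            "medium_exchanges": self.medium_exchanges,
            "medium": self.medium,
            "provenance": self.provenance,
        }
        return spec

    @classmethod
    def from_modelspec(cls, spec: ModelSpec) -> "CommunityModel":
        meta = dict(spec.meta)
        state = meta.pop("community")
        cm = cls(
            id=spec.id,
            name=spec.name,
            compartments=dict(spec.compartments),
            metabolites=spec.metabolites,
            reactions=spec.reactions,
            genes=list(spec.genes),
            objective=spec.objective,
            meta=meta,
            members=[MemberRecord(**m) for m in state["members"]],
            medium_compartment=state["medium_compartment"],
            budget_metabolite_id=state["budget_metabolite_id"],
            budget_reaction_id=state["budget_reaction_id"],
            community_biomass_reaction_id=state["community_biomass_reaction_id"],
            dummy_registry={
                rid: [(d, kind, float(value)) for d, kind, value in entries]
                for rid, entries in state["dummy_registry"].items()
            },
            split_registry=state["split_registry"],
            mode=state["mode"],
            mu=state["mu"],
            fractions=state["fractions"],
            member_exchanges=state["member_exchanges"],
            medium_exchanges=state["medium_exchanges"],
            medium=state["medium"],
            provenance=state["provenance"],
        )
        # the annotation payload is the authoritative state record: re-apply
        # it so mode-dependent bounds/coefficients are restored at full
        # precision (SBML serialises doubles at ~15 significant digits)
        if cm.medium:
            set_medium(cm, cm.medium)
        if cm.mode == "fixed_abundance" and cm.fractions is not None:
            set_fixed_abundance(cm, cm.fractions)
        elif cm.mode == "fixed_growth" and cm.mu is not None:
            set_fixed_growth(cm, cm.mu)
        return cm

    def member(self, name: str) -> MemberRecord:
        for m in self.members:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def member_names(self) -> list[str]:
        return [m.name for m in self.members]

    # -- convenience delegates ----------------------------------------------
    def set_medium(self, medium: dict[str, float]) -> None:
        set_medium(self, medium)

    def set_fixed_abundance(self, fractions: dict[str, float]) -> None:
        set_fixed_abundance(self, fractions)

    def set_fixed_growth(self, mu: float) -> None:
        set_fixed_growth(self, mu)

    def net_flux_combination(self, original_rid: str) -> dict[str, float]:
        """Coefficients expressing the net flux of an original member reaction
        in terms of its irreversible parts."""
        entry = self.split_registry[original_rid]
        combo: dict[str, float] = {}
        if entry["flipped"]:
            combo[entry["reverse"]] = -1.0
        else:
            combo[entry["forward"]] = 1.0
            if entry["reverse"]:
                combo[entry["reverse"]] = -1.0
        return combo


def split_reversible(reaction: ReactionSpec) -> list[ReactionSpec]:
    """Decompose a reaction into irreversible parts (lb ≥ 0 each).

    Reversible reactions yield a forward copy (same id) and a reverse copy
    (id + ``"__rev"``, negated stoichiometry); reverse-only reactions yield a
    single flipped copy (id + ``"__flip"``).  Already-irreversible reactions
    are returned unchanged (as a copy).
    """
    lb, ub = reaction.lower_bound, reaction.upper_bound
    if lb >= 0:
        return [reaction.copy()]
    if ub <= 0:
        flip = reaction.copy()
        flip.id = reaction.id + "__flip"
        flip.stoichiometry = {k: -v for k, v in flip.stoichiometry.items()}
        flip.lower_bound, flip.upper_bound = -ub, -lb
        return [flip]
    fwd = reaction.copy()
    fwd.lower_bound = 0.0
    rev = reaction.copy()
    rev.id = reaction.id + "__rev"
    rev.stoichiometry = {k: -v for k, v in rev.stoichiometry.items()}
    rev.lower_bound, rev.upper_bound = 0.0, -lb
    return [fwd, rev]


def apply_bound_free_transform(
    member: PreparedMember,
    fraction_reaction: str,
    budget_metabolite: str,
) -> tuple[ModelSpec, dict, dict]:
    """Convert a prepared member into its bound-free fragment.

    Returns ``(fragment, dummy_registry, split_registry)``.  The fragment's
    member reactions carry only structural bounds ``(0, DEFAULT_BOUND)``; all
    member-specific constraints live in the stoichiometry of dummy
    metabolites tied to the fraction reaction.  The member's own
    medium-boundary reactions are left untouched (they carry absolute,
    environment-level bounds and are replaced during merging).
    """
    fragment = member.model.copy()
    skip = set(member.medium_boundaries.values())
    dummy_registry: dict[str, list[tuple[str, str, float]]] = {}
    split_registry: dict[str, dict] = {}
    fraction_rxn = ReactionSpec(
        id=fraction_reaction,
        name=f"mass fraction of {member.name}",
        stoichiometry={budget_metabolite: -1.0},
        lower_bound=0.0,
        upper_bound=1.0,
    )
    new_reactions: list[ReactionSpec] = []
    new_metabolites: list[MetaboliteSpec] = []
    for rxn in fragment.reactions:
        if rxn.id in skip:
            new_reactions.append(rxn)
            continue
        parts = split_reversible(rxn)
        if len(parts) == 2:
            split_registry[rxn.id] = {
                "forward": parts[0].id, "reverse": parts[1].id, "flipped": False,
            }
        elif parts[0].id.endswith("__flip"):
            split_registry[rxn.id] = {
                "forward": None, "reverse": parts[0].id, "flipped": True,
            }
        else:
            split_registry[rxn.id] = {
                "forward": parts[0].id, "reverse": None, "flipped": False,
            }
        for part in parts:
            entries: list[tuple[str, str, float]] = []
            if part.upper_bound < 0:  # split_reversible guarantees lb >= 0
                raise IntegrityError(
                    f"irreversible part {part.id!r} has negative upper bound"
                )
            ub_val = part.upper_bound
            dummy_ub = f"D_ub__{part.id}"
            new_metabolites.append(
                MetaboliteSpec(
                    id=dummy_ub,
                    name=f"upper-bound dummy for {part.id}",
                    compartment_id=MEDIUM_COMPARTMENT,
                )
            )
            part.stoichiometry[dummy_ub] = part.stoichiometry.get(dummy_ub, 0.0) - 1.0
            if ub_val != 0:
                fraction_rxn.stoichiometry[dummy_ub] = ub_val
            new_reactions_sink = ReactionSpec(
                id=f"SK_{dummy_ub}",
                name=f"slack sink for {dummy_ub}",
                stoichiometry={dummy_ub: -1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            )
            entries.append((dummy_ub, "ub", ub_val))
            lb_sink = None
            if part.lower_bound > 0:
                dummy_lb = f"D_lb__{part.id}"
                new_metabolites.append(
                    MetaboliteSpec(
                        id=dummy_lb,
                        name=f"lower-bound dummy for {part.id}",
                        compartment_id=MEDIUM_COMPARTMENT,
                    )
                )
                part.stoichiometry[dummy_lb] = 1.0
                fraction_rxn.stoichiometry[dummy_lb] = -part.lower_bound
                lb_sink = ReactionSpec(
                    id=f"SK_{dummy_lb}",
                    name=f"slack sink for {dummy_lb}",
                    stoichiometry={dummy_lb: -1.0},
                    lower_bound=0.0,
                    upper_bound=DEFAULT_BOUND,
                )
                entries.append((dummy_lb, "lb", part.lower_bound))
            part.lower_bound, part.upper_bound = 0.0, DEFAULT_BOUND
            dummy_registry[part.id] = entries
            new_reactions.append(part)
            new_reactions.append(new_reactions_sink)
            if lb_sink is not None:
                new_reactions.append(lb_sink)
    new_reactions.append(fraction_rxn)
    fragment.metabolites.extend(new_metabolites)
    fragment.reactions = new_reactions
    return fragment, dummy_registry, split_registry


def original_bounds(cm: CommunityModel, original_rid: str) -> tuple[float, float]:
    """Recover a member reaction's original flux bounds from the dummy
    registry (the inverse of the bound-free transform)."""

    def value(part_id: str, kind: str) -> float | None:
        for _, k, v in cm.dummy_registry[part_id]:
            if k == kind:
                return v
        return None

    entry = cm.split_registry[original_rid]
    if entry["flipped"]:
        ub_flip = value(entry["reverse"], "ub")
        lb_flip = value(entry["reverse"], "lb") or 0.0
        return (-ub_flip, -lb_flip)
    if entry["reverse"]:
        return (-value(entry["reverse"], "ub"), value(entry["forward"], "ub"))
    lb = value(entry["forward"], "lb") or 0.0
    return (lb, value(entry["forward"], "ub"))


def _biomass_parts(cm_split: dict, biomass_rid: str) -> list[tuple[str, float]]:
    """(part id, sign) pairs whose signed sum is the net biomass flux."""
    entry = cm_split[biomass_rid]
    parts = []
    if entry["flipped"]:
        parts.append((entry["reverse"], -1.0))
    else:
        parts.append((entry["forward"], 1.0))
        if entry["reverse"]:
            parts.append((entry["reverse"], -1.0))
    return parts


def build_community_model(
    members: list[PreparedMember],
    match_mode: str = "id",
    database: str | None = None,
    name: str = "community",
) -> CommunityModel:
    """Merge prepared members into one bound-free community model.

    The returned model starts in fixed-abundance mode at equal fractions with
    all medium uptake closed (apply :func:`set_medium` to open a medium).
    """
    if not members:
        raise CommgemError("a community needs at least one member")
    names = [m.name for m in members]
    if len(set(names)) != len(names):
        raise CommgemError(f"duplicate member names: {sorted(names)}")

    if match_mode == "id":
        table = match_by_id(members)
    elif match_mode == "annotation":
        if database is None:
            raise CommgemError("annotation matching requires a database name")
        table = match_by_annotation(members, database)
    else:
        raise CommgemError(f"unknown match mode {match_mode!r}")
    medium_fragment, match_prov = merge_into_medium(members, table)
    retarget = match_prov["retarget"]

    cm = CommunityModel(
        id=sanitize_sid(name),
        name=name,
        compartments={MEDIUM_COMPARTMENT: "shared growth medium"},
    )
    cm.meta["match_conflicts"] = match_prov["conflicts"]

    # shared medium species and community boundary reactions
    for met in medium_fragment.metabolites:
        cm.metabolites.append(met)
        cm.provenance[met.id] = "community"
    for rxn in medium_fragment.reactions:
        cm.reactions.append(rxn)
        cm.provenance[rxn.id] = "community"
        (gid,) = rxn.stoichiometry
        cm.medium_exchanges[gid] = rxn.id

    # abundance budget: ∅ → budget at fixed rate 1, consumed by the F_i
    cm.metabolites.append(
        MetaboliteSpec(
            id=BUDGET_METABOLITE,
            name="community abundance budget",
            compartment_id=MEDIUM_COMPARTMENT,
        )
    )
    cm.provenance[BUDGET_METABOLITE] = "community"
    cm.reactions.append(
        ReactionSpec(
            id=BUDGET_REACTION,
            name="abundance budget source",
            stoichiometry={BUDGET_METABOLITE: 1.0},
            lower_bound=1.0,
            upper_bound=1.0,
        )
    )
    cm.provenance[BUDGET_REACTION] = "community"

    for member in members:
        fraction_id = f"{member.name}_fraction"
        fragment, dummies, splits = apply_bound_free_transform(
            member, fraction_id, BUDGET_METABOLITE
        )
        cm.dummy_registry.update(dummies)
        cm.split_registry.update(splits)

        twin_to_group = {
            met: gid for (mname, met), gid in retarget.items() if mname == member.name
        }
        own_boundaries = set(member.medium_boundaries.values())
        for cid, cname in fragment.compartments.items():
            if cid == MEDIUM_COMPARTMENT:
                continue
            cm.compartments[cid] = cname
            cm.provenance[cid] = member.name
        for met in fragment.metabolites:
            if met.id in twin_to_group:
                continue  # shared medium species comes from the merged fragment
            cm.metabolites.append(met)
            cm.provenance[met.id] = member.name
        for rxn in fragment.reactions:
            if rxn.id in own_boundaries:
                continue  # replaced by the community boundary reaction
            if any(met in twin_to_group for met in rxn.stoichiometry):
                rxn.stoichiometry = {
                    twin_to_group.get(met, met): coeff
                    for met, coeff in rxn.stoichiometry.items()
                }
            cm.reactions.append(rxn)
            cm.provenance[rxn.id] = member.name
        for gene in fragment.genes:
            cm.genes.append(gene)
            cm.provenance[gene] = member.name

        # biomass species X_i and growth-coupling dummy G_i
        x_id = f"X_{member.name}"
        g_id = f"G_{member.name}"
        for mid, mname_ in ((x_id, f"biomass of {member.name}"),
                            (g_id, f"growth coupling dummy for {member.name}")):
            cm.metabolites.append(
                MetaboliteSpec(id=mid, name=mname_, compartment_id=MEDIUM_COMPARTMENT)
            )
            cm.provenance[mid] = member.name
        for part_id, sign in _biomass_parts(splits, member.biomass_reaction_id):
            cm.reaction(part_id).stoichiometry[x_id] = sign
        sink_id = f"SK_{x_id}"
        cm.reactions.append(
            ReactionSpec(
                id=sink_id,
                name=f"biomass sink for {member.name}",
                stoichiometry={x_id: -1.0},
                lower_bound=0.0,
                upper_bound=0.0,
            )
        )
        cm.provenance[sink_id] = member.name

        cm.member_exchanges[member.name] = {
            twin_to_group.get(met, met): rid
            for met, rid in member.exchange_transports.items()
        }
        cm.members.append(
            MemberRecord(
                name=member.name,
                biomass_reaction_id=member.biomass_reaction_id,
                fraction_reaction_id=fraction_id,
                biomass_metabolite_id=x_id,
                growth_coupling_metabolite_id=g_id,
                biomass_sink_reaction_id=sink_id,
            )
        )

    cm.reactions.append(
        ReactionSpec(
            id=COMMUNITY_BIOMASS,
            name="community biomass",
            stoichiometry={},  # filled by the mode setters
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )
    )
    cm.provenance[COMMUNITY_BIOMASS] = "community"
    # provenance for machinery ids created alongside member reactions
    for rid, entries in cm.dummy_registry.items():
        owner = cm.provenance.get(rid)
        for dummy, _, _ in entries:
            cm.provenance.setdefault(dummy, owner or "community")
            cm.provenance.setdefault(f"SK_{dummy}", owner or "community")
    for member in members:
        cm.provenance[f"{member.name}_fraction"] = member.name
    cm.objective = (COMMUNITY_BIOMASS, "max")

    n = len(members)
    set_fixed_abundance(cm, {m.name: 1.0 / n for m in members})
    cm.validate()
    return cm


def set_medium(cm: CommunityModel, medium: dict[str, float]) -> None:
    """Apply a growth medium (medium metabolite id → max uptake flux).

    Listed metabolites get uptake opened to the stated flux; every other
    community boundary is closed for uptake.  Secretion stays open.  Fully
    overrides any previously applied medium.
    """
    unknown = sorted(set(medium) - set(cm.medium_exchanges))
    if unknown:
        raise CommgemError(
            f"unknown medium metabolites {unknown}; valid ids: "
            f"{sorted(cm.medium_exchanges)}"
        )
    for gid, rid in cm.medium_exchanges.items():
        rxn = cm.reaction(rid)
        rxn.lower_bound = -float(medium[gid]) if gid in medium else 0.0
    cm.medium = {k: float(v) for k, v in medium.items()}


def _clear_growth_coupling(cm: CommunityModel) -> None:
    for member in cm.members:
        g_id = member.growth_coupling_metabolite_id
        cm.reaction(member.fraction_reaction_id).stoichiometry.pop(g_id, None)
        for part_id, _ in _biomass_parts(cm.split_registry, member.biomass_reaction_id):
            cm.reaction(part_id).stoichiometry.pop(g_id, None)


def set_fixed_abundance(cm: CommunityModel, fractions: dict[str, float]) -> None:
    """Clamp the community composition; the growth rate becomes the free
    (optimised) variable.

    Only bounds and coefficients change — no re-merge happens and no reaction
    objects are created or destroyed.
    """
    if set(fractions) != set(cm.member_names):
        raise CommgemError(
            f"fractions must cover exactly the members {sorted(cm.member_names)}"
        )
    for name, f in fractions.items():
        if f < -1e-12:
            raise CommgemError(f"negative fraction {f} for member {name!r}")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise CommgemError(f"fractions sum to {total!r}, expected 1")

    _clear_growth_coupling(cm)
    biomass_stoich: dict[str, float] = {}
    for member in cm.members:
        f = max(float(fractions[member.name]), 0.0)
        frac_rxn = cm.reaction(member.fraction_reaction_id)
        frac_rxn.lower_bound = frac_rxn.upper_bound = f
        sink = cm.reaction(member.biomass_sink_reaction_id)
        sink.lower_bound = sink.upper_bound = 0.0
        if f > TOLERANCE:
            biomass_stoich[member.biomass_metabolite_id] = -f
    combio = cm.reaction(cm.community_biomass_reaction_id)
    combio.stoichiometry.clear()
    combio.stoichiometry.update(biomass_stoich)
    combio.lower_bound, combio.upper_bound = 0.0, DEFAULT_BOUND
    cm.mode = "fixed_abundance"
    cm.fractions = {k: float(v) for k, v in fractions.items()}
    cm.mu = None


def set_fixed_growth(cm: CommunityModel, mu: float) -> None:
    """Clamp the community growth rate; the composition becomes free.

    Balanced growth ``V_bio,i = μ·f_i`` is enforced exactly through a
    per-member coupling dummy ``G_i`` produced by ``F_i`` with coefficient μ
    and consumed 1:1 by the member's biomass reaction.  Changing μ rewrites
    only those coefficients.
    """
    if mu < 0:
        raise CommgemError(f"growth rate must be non-negative, got {mu}")
    _clear_growth_coupling(cm)
    combio_stoich: dict[str, float] = {}
    for member in cm.members:
        g_id = member.growth_coupling_metabolite_id
        frac_rxn = cm.reaction(member.fraction_reaction_id)
        frac_rxn.lower_bound, frac_rxn.upper_bound = 0.0, 1.0
        if mu != 0:
            frac_rxn.stoichiometry[g_id] = float(mu)
        for part_id, sign in _biomass_parts(cm.split_registry, member.biomass_reaction_id):
            cm.reaction(part_id).stoichiometry[g_id] = -sign
        sink = cm.reaction(member.biomass_sink_reaction_id)
        sink.lower_bound, sink.upper_bound = 0.0, DEFAULT_BOUND
        combio_stoich[member.biomass_metabolite_id] = -1.0  # feasibility placeholder
    combio = cm.reaction(cm.community_biomass_reaction_id)
    combio.stoichiometry.clear()
    combio.stoichiometry.update(combio_stoich)
    combio.lower_bound, combio.upper_bound = 0.0, DEFAULT_BOUND
    cm.mode = "fixed_growth"
    cm.mu = float(mu)
    cm.fractions = None
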