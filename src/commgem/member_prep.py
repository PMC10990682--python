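"""Preparation of single-organism models for merging into a community.

Preparation prefixes every organism-owned identifier with the member name,
adds the shared medium compartment, and rewrites each boundary reaction as a
transport into the medium (keeping its original flux bounds verbatim) plus a
new community-level boundary reaction on the medium twin metabolite.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

from .config import DEFAULT_BOUND
from .errors import AmbiguousExchangeError, BiomassError, CommgemError
from .model_core import (
    MetaboliteSpec,
    ModelSpec,
    ReactionSpec,
    check_balance,
    is_valid_sid,
    sanitize_ids,
    sanitize_sid,
)

logger = logging.getLogger("commgem")

MEDIUM_COMPARTMENT = "medium"

__all__ = [
    "PreparedMember",
    "prefix_member",
    "strip_prefix",
    "convert_boundaries",
    "identify_biomass",
    "prepare_member",
    "MEDIUM_COMPARTMENT",
]


@dataclass
class PreparedMember:
    """A member model that is prefixed and medium-ready."""

    name: str
    model: ModelSpec
    biomass_reaction_id: str
    boundary_metabolite_ids: list[str]
    source_digest: str
    #: medium twin metabolite id → transport reaction id (member ↔ medium,
    #: positive flux = secretion into the medium)
    exchange_transports: dict[str, str] = field(default_factory=dict)
    #: medium twin metabolite id → this member's own boundary reaction id
    medium_boundaries: dict[str, str] = field(default_factory=dict)


def prefix_member(model: ModelSpec, name: str) -> ModelSpec:
    """Prefix every compartment, metabolite, reaction and gene id with ``name_``.

    The mapping is trivially invertible (see :func:`strip_prefix`).
    """
    if not name:
        raise CommgemError("member name must not be empty")
    if not is_valid_sid(name):
        raise CommgemError(f"member name {name!r} is not SId-safe; sanitize it first")
    out = model.copy()
    pre = name + "_"
    out.compartments = {pre + k: v for k, v in out.compartments.items()}
    gene_map = {g: pre + g for g in out.genes}
    for m in out.metabolites:
        m.id = pre + m.id
        m.compartment_id = pre + m.compartment_id
    for r in out.reactions:
        r.id = pre + r.id
        r.stoichiometry = {pre + k: v for k, v in r.stoichiometry.items()}
        if r.gene_association:
            from .model_core import _rename_gene_association

            r.gene_association = _rename_gene_association(r.gene_association, gene_map)
    out.genes = [pre + g for g in out.genes]
    if out.objective is not None:
        out.objective = (pre + out.objective[0], out.objective[1])
    return out


def strip_prefix(model: ModelSpec, name: str) -> ModelSpec:
    """Inverse of :func:`prefix_member` (only for fully prefixed models)."""
    pre = name + "_"

    def strip(ident: str) -> str:
        if not ident.startswith(pre):
            raise CommgemError(f"id {ident!r} does not carry prefix {pre!r}")
        return ident[len(pre):]

    out = model.copy()
    out.compartments = {strip(k): v for k, v in out.compartments.items()}
    gene_map = {g: strip(g) for g in out.genes}
    for m in out.metabolites:
        m.id = strip(m.id)
        m.compartment_id = strip(m.compartment_id)
    for r in out.reactions:
        r.id = strip(r.id)
        r.stoichiometry = {strip(k): v for k, v in r.stoichiometry.items()}
        if r.gene_association:
            from .model_core import _rename_gene_association

            r.gene_association = _rename_gene_association(r.gene_association, gene_map)
    out.genes = [strip(g) for g in out.genes]
    if out.objective is not None:
        out.objective = (strip(out.objective[0]), out.objective[1])
    return out


def medium_twin_id(met_id: str, compartment_id: str, prefix: str | None = None) -> str:
    """Medium twin id: the original (unprefixed) metabolite id with its
    compartment suffix replaced by ``_medium``.

    ``glc__D_e`` (compartment ``e``) → ``glc__D_medium``; ids not ending in
    their compartment id simply get ``_medium`` appended.
    """
    original = met_id
    comp = compartment_id
    if prefix:
        pre = prefix + "_"
        if original.startswith(pre):
            original = original[len(pre):]
        if comp.startswith(pre):
            comp = comp[len(pre):]
    if original.endswith("_" + comp):
        return original[: -(len(comp) + 1)] + "_" + MEDIUM_COMPARTMENT
    return original + "_" + MEDIUM_COMPARTMENT


def convert_boundaries(
    model: ModelSpec, medium_compartment: str = MEDIUM_COMPARTMENT,
    prefix: str | None = None,
) -> ModelSpec:
    """Rewrite boundary reactions as member↔medium transports.

    For each boundary reaction over member metabolite ``m`` a medium twin of
    ``m`` is created, the boundary reaction becomes the transport
    ``m ↔ m_medium`` with its original bounds, and a new boundary reaction
    ``m_medium → ∅`` is added with uptake closed (lb = 0) pending
    :func:`~commgem.assembly.set_medium`.  Demand/sink reactions are treated
    identically.
    """
    out = model.copy()
    out.compartments.setdefault(medium_compartment, "shared growth medium")
    mets = {m.id: m for m in out.metabolites}
    seen_boundary: dict[str, str] = {}
    twin_ids: set[str] = set()
    new_boundaries: list[ReactionSpec] = []
    for r in out.reactions:
        if not r.is_boundary:
            continue
        if len(r.stoichiometry) != 1:
            raise AmbiguousExchangeError(
                f"boundary reaction {r.id!r} involves more than one metabolite"
            )
        (met_id, coeff), = r.stoichiometry.items()
        if met_id in seen_boundary:
            raise AmbiguousExchangeError(
                f"metabolite {met_id!r} has two boundary reactions: "
                f"{seen_boundary[met_id]!r} and {r.id!r}"
            )
        seen_boundary[met_id] = r.id
        member_met = mets[met_id]
        twin = medium_twin_id(met_id, member_met.compartment_id, prefix)
        if twin not in twin_ids and twin not in mets:
            twin_met = member_met.copy()
            twin_met.id = twin
            twin_met.compartment_id = medium_compartment
            out.metabolites.append(twin_met)
            twin_ids.add(twin)
            boundary = ReactionSpec(
                id=f"EX_{twin}",
                name=f"community exchange of {twin}",
                stoichiometry={twin: -1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            )
            new_boundaries.append(boundary)
        # rewrite boundary as transport, original bounds retained
        r.stoichiometry = {met_id: coeff, twin: -coeff}
        r.name = r.name or f"transport of {twin} for {prefix or model.id}"
    out.reactions.extend(new_boundaries)
    return out


def identify_biomass(model: ModelSpec, hint: str | None = None) -> str:
    """Find the member's biomass reaction.

    Priority: explicit hint, then the model objective, then the unique
    reaction whose id contains "biomass" (case-insensitive).
    """
    rxn_ids = set(model.reaction_ids)
    if hint is not None:
        if hint in rxn_ids:
            return hint
        raise BiomassError(f"biomass hint {hint!r} not found in model {model.id!r}")
    if model.objective is not None and model.objective[0] in rxn_ids:
        return model.objective[0]
    candidates = [rid for rid in model.reaction_ids if "biomass" in rid.lower()]
    if len(candidates) == 1:
        return candidates[0]
    if not candidates:
        raise BiomassError(f"no biomass reaction identifiable in model {model.id!r}")
    raise BiomassError(
        f"multiple biomass candidates in model {model.id!r}: {sorted(candidates)}"
    )


def _digest(model: ModelSpec) -> str:
    from ._jsonio import model_to_dict

    blob = json.dumps(model_to_dict(model), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def prepare_member(
    model: ModelSpec, name: str, biomass_hint: str | None = None
) -> PreparedMember:
    """Sanitize, prefix and medium-convert one member model.

    Imbalanced internal reactions are logged as warnings, never fatal.
    """
    digest = _digest(model)
    sane, renames = sanitize_ids(model)
    if renames:
        logger.info("member %s: sanitized %d ids", name, len(renames))
    name = name if is_valid_sid(name) else sanitize_sid(name)
    biomass = identify_biomass(sane, renames.get(biomass_hint, biomass_hint) if biomass_hint else None)
    prefixed = prefix_member(sane, name)
    biomass = f"{name}_{biomass}"
    converted = convert_boundaries(prefixed, prefix=name)
    converted.id = name
    converted.validate()

    report = check_balance(converted)
    for rid, entry in report.items():
        if entry.verdict == "unbalanced":
            logger.warning(
                "member %s: reaction %s is unbalanced (mass %s, charge %s)",
                name, rid, dict(entry.mass_delta), entry.charge_delta,
            )

    twins = [m.id for m in converted.metabolites
             if m.compartment_id == MEDIUM_COMPARTMENT]
    twin_set = set(twins)
    transports = {}
    boundaries = {}
    for r in converted.reactions:
        in_medium = [m for m in r.stoichiometry if m in twin_set]
        if r.is_boundary and in_medium:
            boundaries[in_medium[0]] = r.id
        elif in_medium:
            transports[in_medium[0]] = r.id
    return PreparedMember(
        name=name,
        model=converted,
        biomass_reaction_id=biomass,
        boundary_metabolite_ids=twins,
        source_digest=digest,
        exchange_transports=transports,
        medium_boundaries=boundaries,
    )
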