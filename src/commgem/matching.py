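"""Matching of member boundary metabolites in the shared medium compartment.

Two strategies mirror common practice with automatically generated models:
string-equal SBML ids, or cross-references to a chosen annotation database.
Annotation matching is strict: it proceeds only when every boundary metabolite
maps to exactly one identifier in the chosen database, otherwise it stops and
informs the user (suggesting a different database or by-ID matching).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import DEFAULT_BOUND
from .errors import MatchingError
from .member_prep import MEDIUM_COMPARTMENT, PreparedMember
from .model_core import MetaboliteSpec, ModelSpec, ReactionSpec, sanitize_sid

logger = logging.getLogger("commgem")

__all__ = ["MatchTable", "match_by_id", "match_by_annotation", "merge_into_medium"]


@dataclass
class MatchTable:
    """Partition of all member boundary metabolites into medium groups."""

    #: (medium metabolite id, [(member name, member boundary metabolite id), ...])
    groups: list[tuple[str, list[tuple[str, str]]]]
    mode: str  # "id" | "annotation"
    database: str | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"medium_id": gid, "member": member, "member_metabolite_id": met}
            for gid, entries in self.groups
            for member, met in entries
        ]
        return pd.DataFrame(rows, columns=["medium_id", "member", "member_metabolite_id"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_partition(members: list[PreparedMember], table: MatchTable) -> None:
    expected = {(m.name, b) for m in members for b in m.boundary_metabolite_ids}
    got = [(member, met) for _, entries in table.groups for member, met in entries]
    if len(got) != len(set(got)) or set(got) != expected:
        raise MatchingError("match table is not a partition of boundary metabolites")
    gids = [gid for gid, _ in table.groups]
    if len(gids) != len(set(gids)):
        raise MatchingError("duplicate group ids in match table")


def match_by_id(members: list[PreparedMember]) -> MatchTable:
    """Group boundary metabolites whose (unprefixed) medium ids are equal."""
    groups: dict[str, list[tuple[str, str]]] = {}
    for member in members:
        for met_id in member.boundary_metabolite_ids:
            groups.setdefault(met_id, []).append((member.name, met_id))
    table = MatchTable(groups=sorted(groups.items()), mode="id")
    _check_partition(members, table)
    return table


def match_by_annotation(members: list[PreparedMember], database: str) -> MatchTable:
    """Group boundary metabolites by their identifier in ``database``.

    Every boundary metabolite must map to exactly one identifier, otherwise a
    :class:`MatchingError` is raised naming the offender.
    """
    groups: dict[str, list[tuple[str, str]]] = {}
    for member in members:
        for met_id in member.boundary_metabolite_ids:
            met = member.model.metabolite(met_id)
            accs = sorted(met.annotations.get(database, ()))
            if len(accs) != 1:
                what = "no identifier" if not accs else f"{len(accs)} identifiers {accs}"
                raise MatchingError(
                    f"boundary metabolite {met_id!r} of member {member.name!r} has "
                    f"{what} in database {database!r}; choose a different database "
                    f"or match by ID"
                )
            gid = sanitize_sid(f"{accs[0]}_{MEDIUM_COMPARTMENT}")
            groups.setdefault(gid, []).append((member.name, met_id))
    table = MatchTable(groups=sorted(groups.items()), mode="annotation", database=database)
    _check_partition(members, table)
    return table


def merge_into_medium(
    members: list[PreparedMember], table: MatchTable
) -> tuple[ModelSpec, dict]:
    """Build the shared-medium model fragment for a match table.

    Returns the fragment (medium compartment, one species and one community
    boundary reaction per group) and a provenance map with the member-twin →
    group-id retargeting and any formula/charge conflicts observed between
    matched partners.
    """
    _check_partition(members, table)
    by_member = {m.name: m for m in members}
    fragment = ModelSpec(id="medium_fragment",
                         compartments={MEDIUM_COMPARTMENT: "shared growth medium"})
    retarget: dict[tuple[str, str], str] = {}
    conflicts: list[dict] = []
    for gid, entries in table.groups:
        partners = [by_member[name].model.metabolite(met) for name, met in entries]
        # keep the most-specified formula (most elements) among partners
        best = None
        for met in partners:
            if met.formula is not None and (
                best is None or len(met.formula) > len(best.formula)
            ):
                best = met
        formulas = {
            met.formula.to_string() for met in partners if met.formula is not None
        }
        charges = {met.charge for met in partners if met.charge is not None}
        if len(formulas) > 1 or len(charges) > 1:
            conflicts.append(
                {"medium_id": gid, "formulas": sorted(formulas),
                 "charges": sorted(charges, key=str)}
            )
            logger.warning(
                "conflicting formulas/charges for matched metabolite %s: %s / %s",
                gid, sorted(formulas), sorted(charges, key=str),
            )
        annotations: dict[str, set[str]] = {}
        for met in partners:
            for db, accs in met.annotations.items():
                annotations.setdefault(db, set()).update(accs)
        fragment.metabolites.append(
            MetaboliteSpec(
                id=gid,
                name=partners[0].name,
                compartment_id=MEDIUM_COMPARTMENT,
                formula=best.formula if best is not None else None,
                charge=next(iter(charges)) if len(charges) == 1 else None,
                annotations=annotations,
            )
        )
        fragment.reactions.append(
            ReactionSpec(
                id=f"EX_{gid}",
                name=f"community exchange of {gid}",
                stoichiometry={gid: -1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            )
        )
        for name, met in entries:
            retarget[(name, met)] = gid
    provenance = {"retarget": retarget, "conflicts": conflicts}
    return fragment, provenance
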