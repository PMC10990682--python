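"""Community analyses: growth, feasible compositions, exchange profiling.

Three headline computations:

* :func:`max_community_growth` — FBA at a fixed composition;
* :func:`feasible_composition` — per-member feasible mass-fraction intervals
  at a fixed community growth rate (FVA over the fraction reactions);
* :func:`potential_exchanges` — composition-independent exchange metabolite
  and cross-feeding prediction: the composition is left variable and the
  equal-growth (balanced growth) constraint is removed, so a single FVA run
  covers the whole abundance simplex.  The resulting ranges may include
  interactions that are infeasible under balanced community growth; the
  profile records that decoupled growth was used.

:func:`detect_infeasible_cycles` closes every community boundary and looks
for member reactions that can still carry flux — a thermodynamically
infeasible loop sustains flux without any net mass input.

Every analysis snapshots and restores the model state: none of them leaves
the community model mutated.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .assembly import CommunityModel, set_fixed_abundance, set_fixed_growth
from .config import DEFAULT_BOUND, TOLERANCE
from .errors import InfeasibleError
from .model_core import FluxResult, optimize, variability_of_combinations

logger = logging.getLogger("commgem")

__all__ = [
    "CompositionRange",
    "ExchangeRow",
    "ExchangeProfile",
    "max_community_growth",
    "feasible_composition",
    "growth_composition_scan",
    "potential_exchanges",
    "detect_infeasible_cycles",
]


@dataclass
class CompositionRange:
    """Feasible mass-fraction interval per member at growth rate ``mu``."""

    mu: float
    ranges: dict[str, tuple[float, float]]
    feasible: bool = True

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"member": m, "mu": self.mu, "f_min": lo, "f_max": hi}
            for m, (lo, hi) in self.ranges.items()
        ]
        return pd.DataFrame(rows, columns=["member", "mu", "f_min", "f_max"])


@dataclass
class ExchangeRow:
    member: str
    metabolite: str
    min_flux: float
    max_flux: float
    role: str  # producer | consumer | both | none


@dataclass
class ExchangeProfile:
    """Per (member, medium metabolite) flux ranges and trophic roles.

    Sign convention: member→medium positive (secretion).  Computed with the
    composition variable and member growth rates decoupled, so the ranges
    bound every fixed composition's ranges from above.
    """

    rows: list[ExchangeRow]
    community_ranges: dict[str, tuple[float, float]]
    cross_fed: list[str]
    decoupled_growth: bool = True

    def role_of(self, member: str, metabolite: str) -> str:
        for row in self.rows:
            if row.member == member and row.metabolite == metabolite:
                return row.role
        raise KeyError((member, metabolite))

    def range_of(self, member: str, metabolite: str) -> tuple[float, float]:
        for row in self.rows:
            if row.member == member and row.metabolite == metabolite:
                return (row.min_flux, row.max_flux)
        raise KeyError((member, metabolite))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "member": r.member,
                    "metabolite": r.metabolite,
                    "min_flux": r.min_flux,
                    "max_flux": r.max_flux,
                    "role": r.role,
                }
                for r in self.rows
            ],
            columns=["member", "metabolite", "min_flux", "max_flux", "role"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def _edges(self) -> list[tuple[str, str, str]]:
        return [
            (r.member, r.metabolite, r.role)
            for r in self.rows
            if r.role != "none"
        ]

    def to_sif(self, path) -> None:
        with open(path, "w") as fh:
            for member, met, role in self._edges():
                fh.write(f"{member}\t{role}\t{met}\n")

    def to_graph(self) -> nx.DiGraph:
        graph = nx.DiGraph()
        for row in self.rows:
            graph.add_node(row.member, kind="member")
            graph.add_node(row.metabolite, kind="metabolite")
        for member, met, role in self._edges():
            if role in ("producer", "both"):
                graph.add_edge(member, met, role=role)
            if role in ("consumer", "both"):
                graph.add_edge(met, member, role=role)
        return graph

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)


def classify_role(min_flux: float, max_flux: float, tol: float = TOLERANCE) -> str:
    """Trophic role from a (member→medium positive) flux range."""
    can_produce = max_flux > tol
    can_consume = min_flux < -tol
    if can_produce and can_consume:
        return "both"
    if can_produce:
        return "producer"
    if can_consume:
        return "consumer"
    return "none"


@contextmanager
def preserve_state(cm: CommunityModel):
    """Snapshot/restore bounds, stoichiometries and mode state in place."""
    saved = [
        (rxn, rxn.lower_bound, rxn.upper_bound, dict(rxn.stoichiometry))
        for rxn in cm.reactions
    ]
    mode, mu = cm.mode, cm.mu
    fractions = dict(cm.fractions) if cm.fractions is not None else None
    medium = dict(cm.medium)
    try:
        yield cm
    finally:
        for rxn, lb, ub, stoich in saved:
            rxn.lower_bound, rxn.upper_bound = lb, ub
            rxn.stoichiometry.clear()
            rxn.stoichiometry.update(stoich)
        cm.mode, cm.mu, cm.fractions, cm.medium = mode, mu, fractions, medium


def _decouple_growth(cm: CommunityModel) -> None:
    """Variable composition, member growth rates independent."""
    from .assembly import _clear_growth_coupling

    _clear_growth_coupling(cm)
    for member in cm.members:
        frac = cm.reaction(member.fraction_reaction_id)
        frac.lower_bound, frac.upper_bound = 0.0, 1.0
        sink = cm.reaction(member.biomass_sink_reaction_id)
        sink.lower_bound, sink.upper_bound = 0.0, DEFAULT_BOUND
    combio = cm.reaction(cm.community_biomass_reaction_id)
    combio.stoichiometry.clear()
    combio.stoichiometry.update(
        {m.biomass_metabolite_id: -1.0 for m in cm.members}
    )


def max_community_growth(
    cm: CommunityModel, fractions: dict[str, float]
) -> FluxResult:
    """Maximum community growth rate at a fixed abundance profile."""
    with preserve_state(cm):
        set_fixed_abundance(cm, fractions)
        result = optimize(cm, cm.community_biomass_reaction_id, "max")
    if result.status != "optimal":
        logger.warning(
            "community FBA at fractions %s was %s; reporting growth 0",
            fractions, result.status,
        )
        return FluxResult(status=result.status, objective_value=0.0)
    return result


def feasible_composition(cm: CommunityModel, mu: float) -> CompositionRange:
    """Feasible mass-fraction interval of every member at growth rate ``mu``."""
    with preserve_state(cm):
        set_fixed_growth(cm, mu)
        frac_ids = {m.name: m.fraction_reaction_id for m in cm.members}
        try:
            fva = variability_of_combinations(
                cm, {name: {rid: 1.0} for name, rid in frac_ids.items()}
            )
        except InfeasibleError:
            return CompositionRange(
                mu=mu,
                ranges={name: (float("nan"), float("nan")) for name in frac_ids},
                feasible=False,
            )
    ranges = {
        name: (min(max(lo, 0.0), 1.0), min(max(hi, 0.0), 1.0))
        for name, (lo, hi) in fva.items()
    }
    return CompositionRange(mu=mu, ranges=ranges, feasible=True)


def growth_composition_scan(
    cm: CommunityModel, mu_values: list[float]
) -> list[CompositionRange]:
    """`feasible_composition` over a list of growth rates (per-μ infeasibility
    is recorded in the result, not fatal)."""
    return [feasible_composition(cm, mu) for mu in mu_values]


def potential_exchanges(cm: CommunityModel) -> ExchangeProfile:
    """Composition-independent exchange and cross-feeding profile.

    A single FVA run with the composition variable (``Σ f_i = 1``) and the
    balanced-growth constraint removed covers every abundance profile at once.
    Cross-fed metabolites have at least one producing and one consuming member,
    from different members.
    """
    with preserve_state(cm):
        _decouple_growth(cm)
        combos: dict[str, dict[str, float]] = {}
        for member in cm.members:
            for gid, rid in cm.member_exchanges[member.name].items():
                combos[f"{member.name}\t{gid}"] = cm.net_flux_combination(rid)
        for gid, rid in cm.medium_exchanges.items():
            combos[f"EX\t{gid}"] = {rid: 1.0}
        ranges = variability_of_combinations(cm, combos)

    rows: list[ExchangeRow] = []
    community_ranges: dict[str, tuple[float, float]] = {}
    for label, (lo, hi) in ranges.items():
        kind, gid = label.split("\t")
        if kind == "EX":
            community_ranges[gid] = (lo, hi)
        else:
            rows.append(ExchangeRow(kind, gid, lo, hi, classify_role(lo, hi)))

    producers: dict[str, set[str]] = {}
    consumers: dict[str, set[str]] = {}
    for row in rows:
        if row.role in ("producer", "both"):
            producers.setdefault(row.metabolite, set()).add(row.member)
        if row.role in ("consumer", "both"):
            consumers.setdefault(row.metabolite, set()).add(row.member)
    # cross-fed: some member can produce it and a *different* member consume it
    cross_fed = sorted(
        gid
        for gid in set(producers) & set(consumers)
        if len(producers[gid] | consumers[gid]) >= 2
    )
    return ExchangeProfile(
        rows=rows,
        community_ranges=community_ranges,
        cross_fed=cross_fed,
        decoupled_growth=True,
    )


def detect_infeasible_cycles(cm: CommunityModel) -> list[str]:
    """Member reactions able to carry flux with every community boundary closed.

    Such flux needs no net mass input and therefore indicates a
    thermodynamically infeasible cycle.  Fraction machinery stays variable;
    slack sinks and other bookkeeping reactions carry bound slack, not matter,
    and are exempt from flagging.  Returns original member reaction ids.
    """
    with preserve_state(cm):
        _decouple_growth(cm)
        for rid in cm.medium_exchanges.values():
            rxn = cm.reaction(rid)
            rxn.lower_bound = rxn.upper_bound = 0.0
        combos = {
            orig: cm.net_flux_combination(orig) for orig in cm.split_registry
        }
        ranges = variability_of_combinations(cm, combos)
    return sorted(
        orig
        for orig, (lo, hi) in ranges.items()
        if lo < -TOLERANCE or hi > TOLERANCE
    )
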