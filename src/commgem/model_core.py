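"""Domain types and core operations for constraint-based metabolic models.

The in-memory representation is deliberately plain: a :class:`ModelSpec` is a
list of metabolites and reactions plus compartments, genes and an objective.
Flux balance analysis (FBA) solves ``max/min c·v  s.t.  S·v = 0, lb ≤ v ≤ ub``
and flux variability analysis (FVA) computes per-reaction flux ranges over the
same steady-state polytope.
"""

from __future__ import annotations

import copy
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .config import DEFAULT_BOUND, TOLERANCE
from .errors import FormatError, IdCollisionError, IntegrityError

logger = logging.getLogger("commgem")

__all__ = [
    "ElementalFormula",
    "MetaboliteSpec",
    "ReactionSpec",
    "ModelSpec",
    "FluxResult",
    "ReactionBalance",
    "BalanceReport",
    "read_model",
    "write_model",
    "sanitize_ids",
    "check_balance",
    "optimize",
    "flux_variability",
    "variability_of_combinations",
]

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*(?:\.\d+)?)")
_SID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

_VALID_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu".split()
)


class ElementalFormula(dict):
    """Element-symbol → count mapping in Hill notation order.

    An empty formula means "unknown".  Polymer-style formulas (``R`` groups,
    ``X``, ``*``) cannot be represented and parse to ``None``.
    """

    @classmethod
    def from_string(cls, text: str | None) -> "ElementalFormula | None":
        """Parse a Hill-notation formula string such as ``C6H12O6``.

        Returns ``None`` for formulas containing non-element groups.
        """
        if text is None:
            return None
        text = text.strip()
        if not text:
            return cls()
        pos = 0
        counts: dict[str, float] = {}
        for match in _ELEMENT_RE.finditer(text):
            if match.start() != pos:
                return None
            symbol, count = match.group(1), match.group(2)
            if symbol not in _VALID_ELEMENTS:
                return None
            n = float(count) if count else 1.0
            counts[symbol] = counts.get(symbol, 0.0) + n
            pos = match.end()
        if pos != len(text):
            return None
        return cls(counts)

    def to_string(self) -> str:
        """Hill notation: C first, H second, then alphabetical."""
        def key(sym: str) -> tuple:
            return ({"C": 0, "H": 1}.get(sym, 2), sym)

        parts = []
        for sym in sorted(self, key=key):
            n = self[sym]
            if n == 0:
                continue
            if float(n).is_integer():
                parts.append(f"{sym}{int(n) if n != 1 else ''}")
            else:
                parts.append(f"{sym}{n}")
        return "".join(parts)

    def scaled(self, factor: float) -> "ElementalFormula":
        return ElementalFormula({k: v * factor for k, v in self.items()})

    def added(self, other: "ElementalFormula") -> "ElementalFormula":
        out = ElementalFormula(self)
        for k, v in other.items():
            out[k] = out.get(k, 0.0) + v
        return out

    def is_zero(self, tol: float = 1e-9) -> bool:
        return all(abs(v) <= tol for v in self.values())


def _copy_annotations(ann: Mapping[str, Iterable[str]]) -> dict[str, set[str]]:
    return {k: set(v) for k, v in ann.items()}


@dataclass
class MetaboliteSpec:
    """One chemical species in one compartment."""

    id: str
    name: str = ""
    compartment_id: str = ""
    formula: ElementalFormula | None = None
    charge: int | None = None
    annotations: dict[str, set[str]] = field(default_factory=dict)

    def copy(self) -> "MetaboliteSpec":
        return MetaboliteSpec(
            id=self.id,
            name=self.name,
            compartment_id=self.compartment_id,
            formula=ElementalFormula(self.formula) if self.formula is not None else None,
            charge=self.charge,
            annotations=_copy_annotations(self.annotations),
        )


@dataclass
class ReactionSpec:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  Bounds are in mmol·gCDW⁻¹·h⁻¹.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_association: str | None = None
    annotations: dict[str, set[str]] = field(default_factory=dict)

    @property
    def is_boundary(self) -> bool:
        """True iff all metabolites are on one side (a system boundary)."""
        if not self.stoichiometry:
            return False
        signs = {c > 0 for c in self.stoichiometry.values() if c != 0}
        return len(signs) == 1

    def copy(self) -> "ReactionSpec":
        return ReactionSpec(
            id=self.id,
            name=self.name,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gene_association=self.gene_association,
            annotations=_copy_annotations(self.annotations),
        )


@dataclass
class ModelSpec:
    """A single constraint-based model."""

    id: str = "model"
    name: str = ""
    compartments: dict[str, str] = field(default_factory=dict)
    metabolites: list[MetaboliteSpec] = field(default_factory=list)
    reactions: list[ReactionSpec] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    objective: tuple[str, str] | None = None  # (reaction id, "max"|"min")
    meta: dict = field(default_factory=dict)  # JSON-serialisable extras, persisted

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> MetaboliteSpec:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> ReactionSpec:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def copy(self) -> "ModelSpec":
        return ModelSpec(
            id=self.id,
            name=self.name,
            compartments=dict(self.compartments),
            metabolites=[m.copy() for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            objective=self.objective,
            meta=copy.deepcopy(self.meta),
        )

    def validate(self) -> None:
        """Raise :class:`IntegrityError` on dangling references or bad bounds."""
        met_ids = set()
        for m in self.metabolites:
            if m.id in met_ids:
                raise IntegrityError(f"duplicate metabolite id {m.id!r}")
            met_ids.add(m.id)
            if m.compartment_id not in self.compartments:
                raise IntegrityError(
                    f"metabolite {m.id!r} references missing compartment "
                    f"{m.compartment_id!r}"
                )
        rxn_ids = set()
        for r in self.reactions:
            if r.id in rxn_ids:
                raise IntegrityError(f"duplicate reaction id {r.id!r}")
            rxn_ids.add(r.id)
            if not r.stoichiometry:
                raise IntegrityError(f"reaction {r.id!r} has empty stoichiometry")
            for met_id in r.stoichiometry:
                if met_id not in met_ids:
                    raise IntegrityError(
                        f"reaction {r.id!r} references missing metabolite {met_id!r}"
                    )
            if r.lower_bound > r.upper_bound:
                raise IntegrityError(
                    f"reaction {r.id!r} has lower bound {r.lower_bound} above "
                    f"upper bound {r.upper_bound}"
                )
        if self.objective is not None and self.objective[0] not in rxn_ids:
            raise IntegrityError(
                f"objective reaction {self.objective[0]!r} does not exist"
            )


@dataclass
class FluxResult:
    """Outcome of one FBA solve."""

    status: str  # optimal | infeasible | unbounded | error
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)


@dataclass
class ReactionBalance:
    mass_delta: ElementalFormula
    charge_delta: int | float | None
    verdict: str  # balanced | unbalanced | unknown


#: reaction id → ReactionBalance, boundary reactions excluded.
BalanceReport = dict


# ---------------------------------------------------------------------------
# ID sanitation
# ---------------------------------------------------------------------------

def sanitize_sid(raw: str) -> str:
    """Deterministic mapping of an arbitrary string onto the SBML SId grammar.

    Every invalid character becomes ``_``; a leading digit gets a ``_`` prefix.
    """
    out = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not out or out[0].isdigit():
        out = "_" + out
    return out


def is_valid_sid(raw: str) -> bool:
    return bool(_SID_RE.match(raw))


def _rename_gene_association(expr: str, renames: Mapping[str, str]) -> str:
    def repl(match: re.Match) -> str:
        token = match.group(0)
        if token in ("and", "or", "AND", "OR"):
            return token
        return renames.get(token, token)

    return re.sub(r"[^\s()]+", repl, expr)


def sanitize_ids(model: ModelSpec) -> tuple[ModelSpec, dict[str, str]]:
    """Rewrite every identifier to satisfy the SBML SId grammar.

    Returns the sanitised model and the old→new rename map (changed ids only).
    Raises :class:`IdCollisionError` when two distinct ids of the same kind
    collide after sanitation.
    """
    out = model.copy()
    rename: dict[str, str] = {}

    def map_ids(ids: Sequence[str], kind: str) -> dict[str, str]:
        table: dict[str, str] = {}
        seen: dict[str, str] = {}
        for old in ids:
            new = sanitize_sid(old)
            if new in seen and seen[new] != old:
                raise IdCollisionError(
                    f"{kind} ids {seen[new]!r} and {old!r} both sanitize to {new!r}"
                )
            seen[new] = old
            table[old] = new
            if new != old:
                rename[old] = new
        return table

    comp_map = map_ids(list(out.compartments), "compartment")
    met_map = map_ids(out.metabolite_ids, "metabolite")
    rxn_map = map_ids(out.reaction_ids, "reaction")
    gene_map = map_ids(out.genes, "gene")

    out.compartments = {comp_map[k]: v for k, v in out.compartments.items()}
    for m in out.metabolites:
        m.id = met_map[m.id]
        m.compartment_id = comp_map[m.compartment_id]
    for r in out.reactions:
        r.id = rxn_map[r.id]
        r.stoichiometry = {met_map[k]: v for k, v in r.stoichiometry.items()}
        if r.gene_association:
            r.gene_association = _rename_gene_association(r.gene_association, gene_map)
    out.genes = [gene_map[g] for g in out.genes]
    if out.objective is not None:
        out.objective = (rxn_map[out.objective[0]], out.objective[1])
    out.id = sanitize_sid(out.id)
    if out.id != model.id:
        rename[model.id] = out.id
    return out, rename


# ---------------------------------------------------------------------------
# Mass and charge balance
# ---------------------------------------------------------------------------

def check_balance(model: ModelSpec) -> BalanceReport:
    """Elemental and charge balance for every non-boundary reaction.

    A reaction with any formula-less (or charge-less) participant gets verdict
    ``unknown``; boundary reactions are exempt and omitted from the report.
    """
    mets = {m.id: m for m in model.metabolites}
    report: BalanceReport = {}
    for r in model.reactions:
        if r.is_boundary:
            continue
        mass = ElementalFormula()
        charge: float | None = 0.0
        known = True
        for met_id, coeff in r.stoichiometry.items():
            m = mets[met_id]
            if m.formula is None or not m.formula or m.charge is None:
                known = False
                break
            mass = mass.added(m.formula.scaled(coeff))
            charge += coeff * m.charge
        if not known:
            report[r.id] = ReactionBalance(ElementalFormula(), None, "unknown")
            continue
        balanced = mass.is_zero() and abs(charge) <= 1e-9
        report[r.id] = ReactionBalance(
            ElementalFormula({k: v for k, v in mass.items() if abs(v) > 1e-9}),
            charge,
            "balanced" if balanced else "unbalanced",
        )
    return report


# ---------------------------------------------------------------------------
# Linear programming layer (FBA / FVA on the steady-state polytope)
# ---------------------------------------------------------------------------

class _LinearProblem:
    """Cached stoichiometric LP for repeated solves on one model state."""

    def __init__(self, model: ModelSpec):
        self.rxn_index = {r.id: i for i, r in enumerate(model.reactions)}
        met_index = {m.id: i for i, m in enumerate(model.metabolites)}
        n = len(model.reactions)
        rows, cols, vals = [], [], []
        for j, r in enumerate(model.reactions):
            for met_id, coeff in r.stoichiometry.items():
                rows.append(met_index[met_id])
                cols.append(j)
                vals.append(coeff)
        self.S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(model.metabolites), n)
        )
        self.lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        self.ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        self.n = n

    def solve(
        self, objective: np.ndarray, direction: str, fix: Mapping[int, float] | None = None
    ) -> tuple[str, float | None, np.ndarray | None]:
        lb, ub = self.lb, self.ub
        if fix:
            lb, ub = lb.copy(), ub.copy()
            for j, value in fix.items():
                lb[j] = ub[j] = value
        sign = -1.0 if direction == "max" else 1.0
        res = linprog(
            sign * objective,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        if res.status == 0:
            return "optimal", float(sign * res.fun), res.x
        if res.status == 2:
            return "infeasible", None, None
        if res.status == 3:
            return "unbounded", None, None
        return "error", None, None  # pragma: no cover - solver failure surfaced


def optimize(
    model: ModelSpec,
    objective: str | None = None,
    direction: str | None = None,
) -> FluxResult:
    """FBA: optimise one reaction's flux over the steady-state polytope.

    Defaults to the model's declared objective.  Solver failures are returned
    in :attr:`FluxResult.status`, never raised.
    """
    if objective is None:
        if model.objective is None:
            raise IntegrityError("model has no objective and none was given")
        objective, model_direction = model.objective
        direction = direction or model_direction
    direction = direction or "max"
    lp = _LinearProblem(model)
    if objective not in lp.rxn_index:
        raise IntegrityError(f"objective reaction {objective!r} does not exist")
    c = np.zeros(lp.n)
    c[lp.rxn_index[objective]] = 1.0
    status, value, x = lp.solve(c, direction)
    if status != "optimal":
        return FluxResult(status=status)
    fluxes = {r.id: float(x[j]) for r, j in zip(model.reactions, range(lp.n))}
    return FluxResult(status="optimal", objective_value=value, fluxes=fluxes)


def variability_of_combinations(
    model: ModelSpec,
    combinations: Mapping[str, Mapping[str, float]],
    fix: Mapping[str, float] | None = None,
) -> dict[str, tuple[float, float]]:
    """Min/max of arbitrary linear flux combinations over the polytope.

    ``combinations`` maps a label to ``{reaction id: coefficient}``.  Used for
    net fluxes of forward/reverse reaction pairs.  Raises
    :class:`InfeasibleError` when the polytope is empty.
    """
    from .errors import InfeasibleError

    lp = _LinearProblem(model)
    fix_idx = None
    if fix:
        fix_idx = {}
        for rid, value in fix.items():
            if rid not in lp.rxn_index:
                raise IntegrityError(f"cannot fix unknown reaction {rid!r}")
            j = lp.rxn_index[rid]
            r = model.reactions[j]
            if not (r.lower_bound - TOLERANCE <= value <= r.upper_bound + TOLERANCE):
                raise IntegrityError(
                    f"fixed value {value} outside bounds of reaction {rid!r}"
                )
            fix_idx[j] = value
    out: dict[str, tuple[float, float]] = {}
    for label, coeffs in combinations.items():
        c = np.zeros(lp.n)
        for rid, coeff in coeffs.items():
            if rid not in lp.rxn_index:
                raise IntegrityError(f"unknown reaction {rid!r} in combination")
            c[lp.rxn_index[rid]] = coeff
        lo_status, lo, _ = lp.solve(c, "min", fix_idx)
        hi_status, hi, _ = lp.solve(c, "max", fix_idx)
        if lo_status == "infeasible" or hi_status == "infeasible":
            raise InfeasibleError(
                f"flux variability infeasible (while solving {label!r})"
            )
        out[label] = (lo, hi)
    return out


def flux_variability(
    model: ModelSpec,
    reaction_ids: Sequence[str] | None = None,
    fix: Mapping[str, float] | None = None,
) -> dict[str, tuple[float, float]]:
    """FVA: per-reaction (min, max) flux over the steady-state polytope.

    ``fix`` imposes equality bounds on the given reactions.  The result is
    clipped into each reaction's own bounds to absorb solver round-off.
    """
    if reaction_ids is None:
        reaction_ids = model.reaction_ids
    combos = {rid: {rid: 1.0} for rid in reaction_ids}
    raw = variability_of_combinations(model, combos, fix=fix)
    out = {}
    for rid, (lo, hi) in raw.items():
        r = model.reaction(rid)
        lo = min(max(lo, r.lower_bound), r.upper_bound)
        hi = min(max(hi, r.lower_bound), r.upper_bound)
        out[rid] = (lo, hi)
    return out


# ---------------------------------------------------------------------------
# I/O dispatch
# ---------------------------------------------------------------------------

def clamp_bound(value: float, which: str, context: str) -> float:
    """Clamp ±∞ bounds to ±DEFAULT_BOUND, logging the adjustment."""
    if math.isinf(value):
        clamped = DEFAULT_BOUND if value > 0 else -DEFAULT_BOUND
        logger.warning(
            "clamping infinite %s bound of %s to %s", which, context, clamped
        )
        return clamped
    return value


def read_model(path, format: str | None = None) -> ModelSpec:
    """Read a model from SBML L3+FBC or the JSON dialect.

    ``format`` defaults from the file extension (``.json`` → json, else sbml).
    Community models written by :func:`write_model` are restored with their
    member registry, mode and composition state intact.
    """
    from . import _jsonio, _sbml

    path = str(path)
    if format is None:
        format = "json" if path.endswith(".json") else "sbml"
    if format == "sbml":
        model = _sbml.read_sbml(path)
    elif format == "json":
        model = _jsonio.read_json(path)
    else:
        raise FormatError(f"unknown format {format!r}")
    model.validate()
    if model.meta.get("community"):
        from .assembly import CommunityModel

        return CommunityModel.from_modelspec(model)
    return model


def write_model(model: ModelSpec, path, format: str | None = None) -> None:
    """Write a model to SBML L3V1+FBC v2 or the JSON dialect.

    Refuses to write models that violate :meth:`ModelSpec.validate` or whose
    identifiers do not satisfy the SBML SId grammar (run :func:`sanitize_ids`
    first).
    """
    from . import _jsonio, _sbml

    model.validate()
    bad = [
        i
        for i in (
            [model.id]
            + list(model.compartments)
            + model.metabolite_ids
            + model.reaction_ids
            + list(model.genes)
        )
        if not is_valid_sid(i)
    ]
    if bad:
        raise IntegrityError(
            f"ids violate the SBML SId grammar (apply sanitize_ids): {bad[:5]}"
        )
    path = str(path)
    if format is None:
        format = "json" if path.endswith(".json") else "sbml"
    if hasattr(model, "to_modelspec"):
        model = model.to_modelspec()
    if format == "sbml":
        _sbml.write_sbml(model, path)
    elif format == "json":
        _jsonio.write_json(model, path)
    else:
        raise FormatError(f"unknown format {format!r}")
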