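"""Deterministic toy member models and communities with hand-derivable optima.

Biomass stoichiometry in all fixtures is 1:1 substrate→product in abstract
units, so every optimum can be computed by hand.  The three-guild syntrophic
fixture mirrors the topology of an ethanol-fed biogas community (a fermenter
feeding a formate/H2-utilising and an acetate/H2-utilising methanogen); it is
a synthetic stand-in built to reproduce that interaction structure, not the
published genome-scale models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_BOUND
from .errors import CommgemError
from .model_core import ElementalFormula, MetaboliteSpec, ModelSpec, ReactionSpec

__all__ = [
    "FixtureSpec",
    "make_chain_community",
    "make_cycle_community",
    "make_biogas_toy",
    "make_random_member",
    "make_random_community",
]


@dataclass
class FixtureSpec:
    """A named set of member models plus medium and documented oracle values."""

    name: str
    members: list[ModelSpec]
    medium: dict[str, float]
    expected: dict = field(default_factory=dict)

    @property
    def member_names(self) -> list[str]:
        return [m.id for m in self.members]


def _met(mid: str, comp: str, formula: str | None = None, charge: int | None = None,
         annotations: dict | None = None) -> MetaboliteSpec:
    return MetaboliteSpec(
        id=mid,
        name=mid,
        compartment_id=comp,
        formula=ElementalFormula.from_string(formula) if formula else None,
        charge=charge,
        annotations={k: set(v) for k, v in (annotations or {}).items()},
    )


def _rxn(rid: str, stoich: dict[str, float], lb: float, ub: float) -> ReactionSpec:
    return ReactionSpec(id=rid, name=rid, stoichiometry=stoich,
                        lower_bound=lb, upper_bound=ub)


def make_chain_community(n: int = 2, uptake: float = 10.0) -> FixtureSpec:
    """A substrate chain: member 1 imports S₀ and converts it to S₁ via its
    biomass reaction; member k converts S₍k₋₁₎ to S₍k₎.

    Only member 1 has an environmental substrate (exchange bound −``uptake``);
    every downstream member depends on its upstream neighbour.  At equal
    fractions the community optimum is ``uptake``; the chain balance forces
    f₁ ≥ f₂ ≥ … at any common growth rate.  For ``n=2`` this is the ``chain2``
    fixture (members A, B; metabolites S → I → P).
    """
    if n < 1:
        raise CommgemError("chain community needs at least one member")
    if n == 2:
        chem = ["S", "I", "P"]
    else:
        chem = [f"M{k}" for k in range(n + 1)]
        if n == 1:
            chem = ["S", "I"]
    members = []
    for k in range(n):
        name = chr(ord("A") + k) if n <= 26 else f"member{k}"
        sub, prod = chem[k], chem[k + 1]
        ex_lb = -uptake if k == 0 else -DEFAULT_BOUND
        model = ModelSpec(
            id=name,
            name=f"chain member {name}",
            compartments={"c": "cytosol", "e": "extracellular"},
            metabolites=[
                _met(f"{sub}_c", "c", "C", 0, {"toydb": [sub]}),
                _met(f"{sub}_e", "e", "C", 0, {"toydb": [sub]}),
                _met(f"{prod}_c", "c", "C", 0, {"toydb": [prod]}),
                _met(f"{prod}_e", "e", "C", 0, {"toydb": [prod]}),
            ],
            reactions=[
                _rxn(f"EX_{sub}", {f"{sub}_e": -1.0}, ex_lb, DEFAULT_BOUND),
                _rxn(f"T_{sub}", {f"{sub}_e": -1.0, f"{sub}_c": 1.0},
                     -DEFAULT_BOUND, DEFAULT_BOUND),
                _rxn(f"BIO_{name}", {f"{sub}_c": -1.0, f"{prod}_c": 1.0},
                     0.0, DEFAULT_BOUND),
                _rxn(f"T_{prod}", {f"{prod}_c": -1.0, f"{prod}_e": 1.0},
                     -DEFAULT_BOUND, DEFAULT_BOUND),
                _rxn(f"EX_{prod}", {f"{prod}_e": -1.0},
                     -DEFAULT_BOUND, DEFAULT_BOUND),
            ],
            objective=(f"BIO_{name}", "max"),
        )
        members.append(model)
    expected = {
        "equal_fraction_growth": uptake,
        "member_A_standalone_growth": uptake,
    }
    if n == 2:
        expected.update(
            {
                "growth_at_0.5_0.5": uptake,
                "growth_at_0.25_0.75": 0.0,
                "growth_at_1_0": uptake,
                "fA_range_at_mu_uptake": (0.5, 1.0),
                "infeasible_mu": uptake + 1.0,
                "cross_fed": [f"{chem[1]}_medium"],
            }
        )
    return FixtureSpec(
        name=f"chain{n}",
        members=members,
        medium={f"{chem[0]}_medium": uptake},
        expected=expected,
    )


def make_cycle_community() -> FixtureSpec:
    """Two members interconverting formate ↔ H₂ + CO₂ in opposite directions.

    Together the conversions and their medium transports form a closed loop
    that can carry flux with every environmental exchange shut — a
    thermodynamically infeasible cycle.  Growth runs off a separate substrate
    so the cycle and biomass are independent.  Formate is encoded as neutral
    CH2O2 so the conversions are mass- and charge-balanced as written.
    """
    shared = [("for", "CH2O2"), ("h2", "H2"), ("co2", "CO2")]
    members = []
    for name, conv_id, stoich in (
        ("A", "FHL_A", {"for_c": -1.0, "h2_c": 1.0, "co2_c": 1.0}),
        ("B", "FDH_B", {"h2_c": -1.0, "co2_c": -1.0, "for_c": 1.0}),
    ):
        mets = [_met("g_c", "c", "C", 0), _met("g_e", "e", "C", 0),
                _met("w_c", "c", "C", 0), _met("w_e", "e", "C", 0)]
        for mid, formula in shared:
            mets += [_met(f"{mid}_c", "c", formula, 0),
                     _met(f"{mid}_e", "e", formula, 0)]
        reactions = [
            _rxn("EX_g", {"g_e": -1.0}, -10.0, DEFAULT_BOUND),
            _rxn("T_g", {"g_e": -1.0, "g_c": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND),
            _rxn(f"BIO_{name}", {"g_c": -1.0, "w_c": 1.0}, 0.0, DEFAULT_BOUND),
            _rxn("T_w", {"w_c": -1.0, "w_e": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND),
            _rxn("EX_w", {"w_e": -1.0}, -DEFAULT_BOUND, DEFAULT_BOUND),
            _rxn(conv_id, stoich, -DEFAULT_BOUND, DEFAULT_BOUND),
        ]
        for mid, _ in shared:
            reactions += [
                _rxn(f"T_{mid}", {f"{mid}_c": -1.0, f"{mid}_e": 1.0},
                     -DEFAULT_BOUND, DEFAULT_BOUND),
                _rxn(f"EX_{mid}", {f"{mid}_e": -1.0}, -DEFAULT_BOUND, DEFAULT_BOUND),
            ]
        members.append(
            ModelSpec(
                id=name,
                name=f"cycle member {name}",
                compartments={"c": "cytosol", "e": "extracellular"},
                metabolites=mets,
                reactions=reactions,
                objective=(f"BIO_{name}", "max"),
            )
        )
    expected = {
        "cycle_reactions": ["A_FHL_A", "B_FDH_B"],
        "cycle_transports": [
            "A_T_for", "A_T_h2", "A_T_co2", "B_T_for", "B_T_h2", "B_T_co2",
        ],
    }
    return FixtureSpec(
        name="cycle2",
        members=members,
        medium={"g_medium": 10.0},
        expected=expected,
    )


def make_biogas_toy() -> FixtureSpec:
    """Three-guild syntrophic toy community on an ethanol + CO₂ medium.

    DV ferments ethanol to acetate plus either H₂ or formate; MH makes methane
    from formate or from H₂ + CO₂; MB makes methane from acetate or from
    H₂ + CO₂.  Cross-feeding is therefore possible via acetate, H₂, CO₂ and
    formate, with DV the sole ethanol consumer — the interaction structure of
    the published ethanol-fed biogas community, rebuilt at toy scale.
    """

    def guild(name: str, exchanged: list[str], internal: list[str],
              conversions: list[ReactionSpec], biomass: str) -> ModelSpec:
        mets = []
        reactions = []
        for mid in exchanged:
            mets += [_met(f"{mid}_c", "c"), _met(f"{mid}_e", "e")]
            reactions += [
                _rxn(f"T_{mid}", {f"{mid}_c": -1.0, f"{mid}_e": 1.0},
                     -DEFAULT_BOUND, DEFAULT_BOUND),
                _rxn(f"EX_{mid}", {f"{mid}_e": -1.0}, -DEFAULT_BOUND, DEFAULT_BOUND),
            ]
        mets += [_met(f"{mid}_c", "c") for mid in internal]
        reactions += conversions
        return ModelSpec(
            id=name,
            name=f"biogas guild {name}",
            compartments={"c": "cytosol", "e": "extracellular"},
            metabolites=mets,
            reactions=reactions,
            objective=(biomass, "max"),
        )

    dv = guild(
        "DV",
        exchanged=["etoh", "ac", "h2", "for"],
        internal=[],
        conversions=[
            _rxn("BIO_DV", {"etoh_c": -1.0, "ac_c": 1.0, "h2_c": 1.0},
                 0.0, DEFAULT_BOUND),
            _rxn("FERM2_DV", {"etoh_c": -1.0, "ac_c": 1.0, "for_c": 1.0},
                 0.0, DEFAULT_BOUND),
        ],
        biomass="BIO_DV",
    )
    mh = guild(
        "MH",
        exchanged=["for", "h2", "co2", "ch4"],
        internal=["red"],
        conversions=[
            _rxn("HYD_MH", {"h2_c": -1.0, "co2_c": -1.0, "red_c": 1.0},
                 0.0, DEFAULT_BOUND),
            _rxn("FDH_MH", {"for_c": -1.0, "red_c": 1.0, "co2_c": 1.0},
                 0.0, DEFAULT_BOUND),
            _rxn("BIO_MH", {"red_c": -1.0, "ch4_c": 1.0}, 0.0, DEFAULT_BOUND),
        ],
        biomass="BIO_MH",
    )
    mb = guild(
        "MB",
        exchanged=["ac", "h2", "co2", "ch4"],
        internal=["red"],
        conversions=[
            _rxn("ACK_MB", {"ac_c": -1.0, "red_c": 1.0, "co2_c": 1.0},
                 0.0, DEFAULT_BOUND),
            _rxn("HYD_MB", {"h2_c": -1.0, "co2_c": -1.0, "red_c": 1.0},
                 0.0, DEFAULT_BOUND),
            _rxn("BIO_MB", {"red_c": -1.0, "ch4_c": 1.0}, 0.0, DEFAULT_BOUND),
        ],
        biomass="BIO_MB",
    )
    return FixtureSpec(
        name="biogas_toy",
        members=[dv, mh, mb],
        medium={"etoh_medium": 10.0, "co2_medium": 10.0},
        expected={
            "cross_fed": ["ac_medium", "co2_medium", "for_medium", "h2_medium"],
            "sole_ethanol_consumer": "DV",
            "methane_producers": ["MB", "MH"],
        },
    )


def make_random_member(seed: int, n_reactions: int = 6) -> ModelSpec:
    """A seeded random linear pathway: one exchange in, internal conversion
    steps (some reversible, some with forced minimum flux), a biomass step,
    one exchange out.  Identical seed → identical model.
    """
    if n_reactions < 3:
        raise CommgemError("random member needs at least 3 reactions")
    rng = np.random.default_rng(seed)
    n_steps = n_reactions - 2
    mets = [_met(f"m{j}_c", "c") for j in range(n_steps + 1)]
    uptake = round(float(rng.uniform(0.1, 50.0)), 6)
    reactions = [_rxn("EX_m0", {"m0_c": -1.0}, -uptake, DEFAULT_BOUND)]
    for j in range(n_steps):
        rid = f"BIO_step{j}" if j == n_steps - 1 else f"STEP{j}"
        ub = round(float(rng.uniform(0.1, 50.0)), 6)
        kind = rng.choice(["irrev", "rev", "forced"], p=[0.5, 0.35, 0.15])
        if kind == "rev":
            lb = -round(float(rng.uniform(0.1, 50.0)), 6)
        elif kind == "forced":
            lb = round(0.02 * ub, 6)
        else:
            lb = 0.0
        reactions.append(
            _rxn(rid, {f"m{j}_c": -1.0, f"m{j+1}_c": 1.0}, lb, ub)
        )
    reactions.append(
        _rxn(f"EX_m{n_steps}", {f"m{n_steps}_c": -1.0}, 0.0, DEFAULT_BOUND)
    )
    model = ModelSpec(
        id=f"rand{seed}",
        name=f"random pathway member (seed {seed})",
        compartments={"c": "cytosol"},
        metabolites=mets,
        reactions=reactions,
        objective=(f"BIO_step{n_steps - 1}", "max"),
        meta={"generator": {"seed": int(seed), "n_reactions": int(n_reactions)}},
    )
    model.validate()
    return model


def make_random_community(
    seed: int, n_members: int | None = None, max_reactions: int = 15
) -> FixtureSpec:
    """A seeded random community of 2–4 random pathway members."""
    rng = np.random.default_rng(seed)
    if n_members is None:
        n_members = int(rng.integers(2, 5))
    members = []
    for i in range(n_members):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        n_rxn = int(rng.integers(3, max_reactions + 1))
        member = make_random_member(sub_seed, n_rxn)
        member.id = f"R{i}"
        members.append(member)
    return FixtureSpec(
        name=f"random_community_{seed}",
        members=members,
        medium={"m0_medium": 10.0},
        expected={},
    )
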