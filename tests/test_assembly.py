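"""Community assembly: reversible splitting, the bound-free transform,
budget/fraction machinery and the two linearization modes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from commgem.assembly import (
    build_community_model,
    original_bounds,
    set_fixed_abundance,
    set_fixed_growth,
    set_medium,
    split_reversible,
)
from commgem.errors import CommgemError
from commgem.fixtures import (
    make_chain_community,
    make_random_community,
    make_random_member,
)
from commgem.member_prep import prepare_member
from commgem.model_core import ReactionSpec, optimize, variability_of_combinations
from commgem.reference import build_scaled_reference

from conftest import build_fixture, original_uptake_medium


def rxn(lb, ub):
    return ReactionSpec(id="R", stoichiometry={"a": -1.0, "b": 1.0},
                        lower_bound=lb, upper_bound=ub)


# ---------------------------------------------------------------------------
# split_reversible
# ---------------------------------------------------------------------------

def test_split_reversible_pair():
    fwd, rev = split_reversible(rxn(-10.0, 10.0))
    assert (fwd.lower_bound, fwd.upper_bound) == (0.0, 10.0)
    assert (rev.lower_bound, rev.upper_bound) == (0.0, 10.0)
    assert rev.id == "R__rev"
    assert rev.stoichiometry == {"a": 1.0, "b": -1.0}


def test_split_irreversible_unchanged():
    (only,) = split_reversible(rxn(0.0, 10.0))
    assert only == rxn(0.0, 10.0)


def test_split_reverse_only_flipped():
    (flip,) = split_reversible(rxn(-10.0, 0.0))
    assert flip.id == "R__flip"
    assert (flip.lower_bound, flip.upper_bound) == (0.0, 10.0)
    assert flip.stoichiometry == {"a": 1.0, "b": -1.0}


@settings(max_examples=60, derandomize=True)
@given(
    lb=st.floats(-50, 50, allow_nan=False),
    span=st.floats(0, 50, allow_nan=False),
)
def test_split_parts_reconstruct_original_bounds(lb, span):
    """The net flux range of the irreversible parts equals the original bounds."""
    parts = split_reversible(rxn(lb, lb + span))
    lo, hi = 0.0, 0.0
    for part in parts:
        sign = -1.0 if part.id != "R" else 1.0
        lo += min(sign * part.lower_bound, sign * part.upper_bound)
        hi += max(sign * part.lower_bound, sign * part.upper_bound)
    assert lo == pytest.approx(lb, abs=1e-9)
    assert hi == pytest.approx(lb + span, abs=1e-9)


# ---------------------------------------------------------------------------
# bound-free transform semantics
# ---------------------------------------------------------------------------

def test_transformed_flux_cap_scales_with_fraction(chain2):
    """At f_A = 0.4 the substrate uptake bound of 10 becomes 10·0.4: the
    dummy-metabolite coupling rescales every member bound with the fraction
    (growth coupling removed so the cap itself is what limits the flux)."""
    from commgem.analysis import _decouple_growth, preserve_state

    _, members, cm = chain2
    with preserve_state(cm):
        _decouple_growth(cm)
        for record, f in zip(cm.members, (0.4, 0.6)):
            frac_rxn = cm.reaction(record.fraction_reaction_id)
            frac_rxn.lower_bound = frac_rxn.upper_bound = f
        fva = variability_of_combinations(
            cm,
            {
                "uptake": cm.net_flux_combination("A_EX_S"),
                "bio": cm.net_flux_combination("A_BIO_A"),
            },
        )
    assert fva["uptake"][0] == pytest.approx(-4.0, abs=1e-6)  # lb −10 → −10·0.4
    assert fva["bio"][1] == pytest.approx(4.0, abs=1e-6)      # supply-capped


def test_zero_fraction_member_is_silenced(chain2):
    _, members, cm = chain2
    set_fixed_abundance(cm, {"A": 1.0, "B": 0.0})
    combos = {
        orig: cm.net_flux_combination(orig)
        for orig in cm.split_registry
        if orig.startswith("B_")
    }
    ranges = variability_of_combinations(cm, combos)
    for orig, (lo, hi) in ranges.items():
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(0.0, abs=1e-6)


def test_transformed_reactions_carry_only_structural_bounds(chain2):
    _, _, cm = chain2
    for rid in cm.dummy_registry:
        reaction = cm.reaction(rid)
        assert reaction.lower_bound == 0.0
        assert reaction.upper_bound == 1000.0


def test_original_bounds_recoverable_from_dummy_registry(chain2):
    _, members, cm = chain2
    for member in members:
        own_boundaries = set(member.medium_boundaries.values())
        for reaction in member.model.reactions:
            if reaction.id in own_boundaries:
                continue
            assert original_bounds(cm, reaction.id) == (
                reaction.lower_bound, reaction.upper_bound,
            )


# ---------------------------------------------------------------------------
# build_community_model structure
# ---------------------------------------------------------------------------

def test_chain2_structure_counts(chain2):
    _, members, cm = chain2
    frac_ids = [m.fraction_reaction_id for m in cm.members]
    assert len(frac_ids) == 2
    assert len([r for r in cm.reactions if r.id == cm.budget_reaction_id]) == 1
    assert len(cm.medium_exchanges) == 3  # S, I, P
    assert cm.reaction(cm.community_biomass_reaction_id) is not None
    cm.validate()


def test_single_member_community_matches_member_optimum():
    fixture = make_chain_community(n=1)
    member = prepare_member(fixture.members[0], "A")
    cm = build_community_model([member])
    set_medium(cm, original_uptake_medium(member))
    set_fixed_abundance(cm, {"A": 1.0})
    community = optimize(cm).objective_value
    standalone = optimize(fixture.members[0]).objective_value
    assert community == pytest.approx(standalone, abs=1e-6)


def test_duplicate_member_names_rejected():
    fixture = make_chain_community()
    members = [prepare_member(m, "same") for m in fixture.members]
    with pytest.raises(CommgemError, match="duplicate"):
        build_community_model(members)


def test_provenance_total(chain2):
    _, members, cm = chain2
    names = set(cm.member_names) | {"community"}
    for rxn_ in cm.reactions:
        assert cm.provenance.get(rxn_.id) in names
    for met in cm.metabolites:
        assert cm.provenance.get(met.id) in names


# ---------------------------------------------------------------------------
# medium
# ---------------------------------------------------------------------------

def test_set_medium_opens_only_listed_uptakes(chain2):
    _, _, cm = chain2
    ex_s = cm.reaction(cm.medium_exchanges["S_medium"])
    ex_i = cm.reaction(cm.medium_exchanges["I_medium"])
    assert ex_s.lower_bound == -10.0
    assert ex_i.lower_bound == 0.0


def test_empty_medium_means_zero_growth(chain2):
    _, _, cm = chain2
    set_medium(cm, {})
    set_fixed_abundance(cm, {"A": 0.5, "B": 0.5})
    assert optimize(cm).objective_value == pytest.approx(0.0, abs=1e-6)


def test_reapplying_medium_overrides_previous(chain2):
    _, _, cm = chain2
    set_medium(cm, {"I_medium": 5.0})
    assert cm.reaction(cm.medium_exchanges["S_medium"]).lower_bound == 0.0
    assert cm.reaction(cm.medium_exchanges["I_medium"]).lower_bound == -5.0


def test_unknown_medium_metabolite_rejected(chain2):
    _, _, cm = chain2
    with pytest.raises(CommgemError, match="valid ids"):
        set_medium(cm, {"unobtainium_medium": 1.0})


def test_growth_monotone_in_uptake_bound(chain2):
    _, _, cm = chain2
    set_fixed_abundance(cm, {"A": 0.5, "B": 0.5})
    growth = []
    for uptake in (2.0, 5.0, 10.0, 20.0):
        set_medium(cm, {"S_medium": uptake})
        growth.append(optimize(cm).objective_value)
    assert growth == sorted(growth)


# ---------------------------------------------------------------------------
# linearization modes
# ---------------------------------------------------------------------------

def test_fixed_abundance_chain2_hand_lp(chain2):
    _, _, cm = chain2
    for fractions, expected in [
        ({"A": 0.5, "B": 0.5}, 10.0),
        ({"A": 0.25, "B": 0.75}, 0.0),
        ({"A": 1.0, "B": 0.0}, 10.0),
    ]:
        set_fixed_abundance(cm, fractions)
        assert optimize(cm).objective_value == pytest.approx(expected, abs=1e-6)


def test_fraction_sum_must_be_one(chain2):
    _, _, cm = chain2
    with pytest.raises(CommgemError):
        set_fixed_abundance(cm, {"A": 0.6, "B": 0.6})
    with pytest.raises(CommgemError):
        set_fixed_abundance(cm, {"A": 1.4, "B": -0.4})


def test_fixed_growth_chain2_composition_window(chain2):
    _, _, cm = chain2
    set_fixed_growth(cm, 10.0)
    frac = {m.name: m.fraction_reaction_id for m in cm.members}
    fva = variability_of_combinations(
        cm, {name: {rid: 1.0} for name, rid in frac.items()}
    )
    assert fva["A"][0] == pytest.approx(0.5, abs=1e-6)
    assert fva["A"][1] == pytest.approx(1.0, abs=1e-6)


def test_fixed_growth_zero_mu_leaves_simplex_free(chain2):
    _, _, cm = chain2
    set_fixed_growth(cm, 0.0)
    frac = {m.name: m.fraction_reaction_id for m in cm.members}
    fva = variability_of_combinations(
        cm, {name: {rid: 1.0} for name, rid in frac.items()}
    )
    for lo, hi in fva.values():
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(1.0, abs=1e-6)


def test_mode_switches_are_involutive(chain2):
    _, _, cm = chain2
    set_fixed_abundance(cm, {"A": 0.5, "B": 0.5})
    first = optimize(cm).objective_value
    set_fixed_growth(cm, 5.0)
    set_fixed_abundance(cm, {"A": 0.5, "B": 0.5})
    assert optimize(cm).objective_value == pytest.approx(first, abs=1e-9)


def test_recomposition_needs_no_rebuild(chain2):
    """Changing the abundance profile only rewrites bounds/coefficients."""
    fixture, members, cm = chain2
    reaction_objects = {id(r) for r in cm.reactions}
    set_fixed_abundance(cm, {"A": 0.7, "B": 0.3})
    assert {id(r) for r in cm.reactions} == reaction_objects
    fresh_members = [prepare_member(m, m.id) for m in fixture.members]
    fresh = build_community_model(fresh_members)
    set_medium(fresh, fixture.medium)
    set_fixed_abundance(fresh, {"A": 0.7, "B": 0.3})
    assert optimize(cm).objective_value == pytest.approx(
        optimize(fresh).objective_value, abs=1e-6
    )


# ---------------------------------------------------------------------------
# equivalence with the directly-scaled reference (core property)
# ---------------------------------------------------------------------------

def assert_equivalent_at(cm, members, medium, fractions):
    set_fixed_abundance(cm, fractions)
    transformed = optimize(cm)
    reference = optimize(build_scaled_reference(members, fractions, medium))
    assert transformed.status == reference.status
    if transformed.status == "optimal":
        assert transformed.objective_value == pytest.approx(
            reference.objective_value, abs=1e-6
        )


@pytest.mark.parametrize("seed", [101, 202, 303])
def test_bound_free_form_equivalent_to_scaled_bounds(seed, rng):
    fixture = make_random_community(seed)
    members, cm = build_fixture(fixture)
    names = [m.name for m in members]
    for _ in range(4):
        point = rng.dirichlet(np.ones(len(names)))
        assert_equivalent_at(cm, members, fixture.medium, dict(zip(names, point)))


def test_single_random_member_full_fraction_equals_member_optimum():
    member_model = make_random_member(9, n_reactions=7)
    member = prepare_member(member_model, member_model.id)
    cm = build_community_model([member])
    medium = original_uptake_medium(member)
    set_medium(cm, medium)
    set_fixed_abundance(cm, {member.name: 1.0})
    assert optimize(cm).objective_value == pytest.approx(
        optimize(member_model).objective_value, abs=1e-6
    )


def test_budget_conservation_in_optimal_solutions(chain2):
    _, _, cm = chain2
    for fractions in [{"A": 0.5, "B": 0.5}, {"A": 0.8, "B": 0.2}]:
        set_fixed_abundance(cm, fractions)
        result = optimize(cm)
        total = sum(
            result.fluxes[m.fraction_reaction_id] for m in cm.members
        )
        assert total == pytest.approx(1.0, abs=1e-6)
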