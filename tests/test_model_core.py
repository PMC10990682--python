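"""Core model types, I/O, balance checking and the LP layer."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from commgem.errors import FormatError, IdCollisionError, IntegrityError
from commgem.model_core import (
    ElementalFormula,
    MetaboliteSpec,
    ModelSpec,
    ReactionSpec,
    check_balance,
    flux_variability,
    is_valid_sid,
    optimize,
    read_model,
    sanitize_ids,
    sanitize_sid,
    write_model,
)
from commgem.fixtures import make_chain_community, make_random_member

from _bruteforce import brute_force_fba, brute_force_fva


def tiny_model(reactions, metabolites=None, objective=None):
    if metabolites is None:
        met_ids = sorted({m for r in reactions for m in r.stoichiometry})
        metabolites = [MetaboliteSpec(id=m, compartment_id="c") for m in met_ids]
    return ModelSpec(
        id="tiny",
        compartments={"c": "cytosol"},
        metabolites=metabolites,
        reactions=reactions,
        objective=objective,
    )


# ---------------------------------------------------------------------------
# formulas and balance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text,expected",
    [
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("H2O", {"H": 2, "O": 1}),
        ("CHO2", {"C": 1, "H": 1, "O": 2}),
        ("Fe2S2", {"Fe": 2, "S": 2}),
        ("", {}),
    ],
)
def test_formula_parsing(text, expected):
    formula = ElementalFormula.from_string(text)
    assert dict(formula) == pytest.approx(expected)
    # Hill-notation serialisation parses back to the same counts
    assert dict(ElementalFormula.from_string(formula.to_string())) == pytest.approx(
        expected
    )


@pytest.mark.parametrize("text", ["C6H12O6R", "X2", "(C6H10O5)n", "abc"])
def test_polymer_formulas_unparseable(text):
    assert ElementalFormula.from_string(text) is None


def glucose_split_model(product_coeff):
    mets = [
        MetaboliteSpec(id="glc", compartment_id="c",
                       formula=ElementalFormula.from_string("C6H12O6"), charge=0),
        MetaboliteSpec(id="lac", compartment_id="c",
                       formula=ElementalFormula.from_string("C3H6O3"), charge=0),
    ]
    rxn = ReactionSpec(id="SPLIT", stoichiometry={"glc": -1.0, "lac": product_coeff},
                       lower_bound=0.0, upper_bound=10.0)
    return tiny_model([rxn], mets)


def test_balanced_glycolysis_verdict():
    report = check_balance(glucose_split_model(2.0))
    assert report["SPLIT"].verdict == "balanced"


def test_unbalanced_verdict_reports_element_deltas():
    report = check_balance(glucose_split_model(1.0))
    entry = report["SPLIT"]
    assert entry.verdict == "unbalanced"
    assert dict(entry.mass_delta) == pytest.approx({"C": -3, "H": -6, "O": -3})


def test_missing_formula_gives_unknown_verdict():
    model = glucose_split_model(2.0)
    model.metabolites[1].formula = None
    assert check_balance(model)["SPLIT"].verdict == "unknown"


def test_boundary_reactions_exempt_from_balance():
    model = glucose_split_model(2.0)
    model.reactions.append(
        ReactionSpec(id="EX_glc", stoichiometry={"glc": -1.0},
                     lower_bound=-10.0, upper_bound=10.0)
    )
    assert "EX_glc" not in check_balance(model)


@pytest.mark.parametrize("scale", [0.5, 2.0, 7.25])
def test_balance_verdicts_invariant_under_reaction_scaling(scale):
    for coeff in (1.0, 2.0):
        base = check_balance(glucose_split_model(coeff))["SPLIT"].verdict
        scaled_model = glucose_split_model(coeff)
        rxn = scaled_model.reactions[0]
        rxn.stoichiometry = {k: v * scale for k, v in rxn.stoichiometry.items()}
        assert check_balance(scaled_model)["SPLIT"].verdict == base


# ---------------------------------------------------------------------------
# id sanitation
# ---------------------------------------------------------------------------

def test_sanitize_rewrites_invalid_ids_and_records_map():
    model = tiny_model(
        [ReactionSpec(id="R 1", stoichiometry={"glc-D[e]": -1.0},
                      lower_bound=0.0, upper_bound=1.0)],
        [MetaboliteSpec(id="glc-D[e]", compartment_id="c")],
    )
    sane, renames = sanitize_ids(model)
    assert renames["glc-D[e]"] == "glc_D_e_"
    assert renames["R 1"] == "R_1"
    assert sane.reactions[0].stoichiometry == {"glc_D_e_": -1.0}
    assert all(is_valid_sid(i) for i in sane.metabolite_ids + sane.reaction_ids)


def test_sanitize_is_identity_on_valid_model():
    model = make_chain_community().members[0]
    sane, renames = sanitize_ids(model)
    assert renames == {}
    assert sane == model


def test_sanitize_collision_raises():
    model = tiny_model(
        [ReactionSpec(id="R1", stoichiometry={"a-b": -1.0, "a_b": 1.0},
                      lower_bound=0.0, upper_bound=1.0)],
        [MetaboliteSpec(id="a-b", compartment_id="c"),
         MetaboliteSpec(id="a_b", compartment_id="c")],
    )
    with pytest.raises(IdCollisionError):
        sanitize_ids(model)


@settings(max_examples=100, derandomize=True)
@given(st.text(min_size=1, max_size=30))
def test_sanitize_sid_valid_and_idempotent(raw):
    sid = sanitize_sid(raw)
    assert is_valid_sid(sid)
    assert sanitize_sid(sid) == sid


# ---------------------------------------------------------------------------
# LP layer
# ---------------------------------------------------------------------------

def test_chain_member_standalone_optimum():
    member = make_chain_community().members[0]
    result = optimize(member, "BIO_A", "max")
    assert result.status == "optimal"
    assert result.objective_value == pytest.approx(10.0, abs=1e-6)
    # steady state holds in the reported fluxes
    for met in member.metabolite_ids:
        net = sum(
            r.stoichiometry.get(met, 0.0) * result.fluxes[r.id]
            for r in member.reactions
        )
        assert net == pytest.approx(0.0, abs=1e-6)


def test_all_zero_bounds_give_zero_optimum_and_fva():
    member = make_chain_community().members[0].copy()
    for r in member.reactions:
        r.lower_bound = r.upper_bound = 0.0
    assert optimize(member, "BIO_A", "max").objective_value == pytest.approx(0.0)
    fva = flux_variability(member)
    assert all(lo == hi == 0.0 for lo, hi in fva.values())


def test_missing_objective_reaction_raises():
    member = make_chain_community().members[0]
    with pytest.raises(IntegrityError):
        optimize(member, "NOPE", "max")


def test_uncoupled_reversible_exchange_fva_spans_its_bounds():
    # A is replenished by an unconstrained partner, so only EX_A's own bounds
    # limit its flux
    model = tiny_model(
        [
            ReactionSpec(id="EX_A", stoichiometry={"A": -1.0},
                         lower_bound=-5.0, upper_bound=7.0),
            ReactionSpec(id="SRC_A", stoichiometry={"A": 1.0},
                         lower_bound=-1000.0, upper_bound=1000.0),
        ]
    )
    assert flux_variability(model, ["EX_A"])["EX_A"] == pytest.approx((-5.0, 7.0))


def test_fva_with_fixed_biomass_pins_product_exchange():
    member = make_chain_community().members[0]
    fva = flux_variability(member, ["EX_I"], fix={"BIO_A": 10.0})
    assert fva["EX_I"] == pytest.approx((10.0, 10.0), abs=1e-6)


@pytest.mark.parametrize("seed", [3, 11, 27])
def test_fba_and_fva_agree_with_vertex_enumeration(seed):
    """LP results match an independent brute-force vertex oracle (≤6 rxns)."""
    model = make_random_member(seed, n_reactions=5)
    objective = model.objective[0]
    status, best = brute_force_fba(model, objective, "max")
    result = optimize(model, objective, "max")
    assert result.status == status
    if status == "optimal":
        assert result.objective_value == pytest.approx(best, abs=1e-6)
        for rid in model.reaction_ids:
            lo, hi = brute_force_fva(model, rid)
            got = flux_variability(model, [rid])[rid]
            assert got[0] == pytest.approx(lo, abs=1e-6)
            assert got[1] == pytest.approx(hi, abs=1e-6)


def test_fva_sign_symmetry_under_reaction_reversal():
    model = make_random_member(5, n_reactions=5)
    rid = "STEP0"
    lo, hi = flux_variability(model, [rid])[rid]
    flipped = model.copy()
    rxn = flipped.reaction(rid)
    rxn.stoichiometry = {k: -v for k, v in rxn.stoichiometry.items()}
    rxn.lower_bound, rxn.upper_bound = -rxn.upper_bound, -rxn.lower_bound
    flo, fhi = flux_variability(flipped, [rid])[rid]
    assert flo == pytest.approx(-hi, abs=1e-6)
    assert fhi == pytest.approx(-lo, abs=1e-6)


def test_fba_agrees_with_cobrapy_on_written_sbml(tmp_path):
    """Independent cross-check: COBRApy + GLPK solve our SBML identically."""
    cobra = pytest.importorskip("cobra")
    member = make_chain_community().members[0]
    path = tmp_path / "member.xml"
    write_model(member, path)
    cobra_model = cobra.io.read_sbml_model(str(path))
    solution = cobra_model.optimize()
    assert solution.status == "optimal"
    assert solution.objective_value == pytest.approx(
        optimize(member).objective_value, abs=1e-6
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fmt", ["sbml", "json"])
def test_round_trip_identity_all_chain_members(fmt, tmp_path):
    for model in make_chain_community().members:
        model.reactions[0].gene_association = "g1 and (g2 or g3)"
        model.genes = ["g1", "g2", "g3"]
        ext = "xml" if fmt == "sbml" else "json"
        path = tmp_path / f"{model.id}.{ext}"
        write_model(model, path, fmt)
        assert read_model(path, fmt) == model


def test_write_refuses_invalid_sid(tmp_path):
    model = make_chain_community().members[0]
    model.reactions[0].id = "has space"
    with pytest.raises(IntegrityError):
        write_model(model, tmp_path / "bad.xml")


def test_read_sbml_with_dangling_species_reference_raises(tmp_path):
    model = make_chain_community().members[0]
    path = tmp_path / "member.xml"
    write_model(model, path)
    text = path.read_text().replace('species="S_c"', 'species="ghost_c"')
    bad = tmp_path / "broken.xml"
    bad.write_text(text)
    with pytest.raises((IntegrityError, FormatError)):
        read_model(bad)


def test_read_garbage_raises_format_error(tmp_path):
    path = tmp_path / "junk.json"
    path.write_text("{not json")
    with pytest.raises(FormatError):
        read_model(path, "json")


def test_infinite_bounds_clamped_on_sbml_read(tmp_path):
    model = make_chain_community().members[0]
    path = tmp_path / "member.xml"
    write_model(model, path)
    text = path.read_text().replace(
        'value="1000"', 'value="INF"', 1
    )
    inf_path = tmp_path / "inf.xml"
    inf_path.write_text(text)
    loaded = read_model(inf_path)
    assert all(math.isfinite(r.upper_bound) for r in loaded.reactions)
    assert max(r.upper_bound for r in loaded.reactions) == 1000.0
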