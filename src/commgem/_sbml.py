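"""SBML Level 3 Version 1 + FBC version 2 reader/writer built on libsbml.

Bounds are encoded as constant parameters (shared when equal to 0 or to the
global default magnitude, reaction-local otherwise), the objective as an FBC
objective, gene associations as FBC gene-product associations, and database
cross-references as RDF CV terms with identifiers.org URIs.  Community
bookkeeping (member registry, mode, composition) travels in one custom
model-level annotation element so a reloaded model restores its state.
"""

from __future__ import annotations

import json
from xml.sax.saxutils import escape

import libsbml

from .config import DEFAULT_BOUND
from .errors import FormatError
from .model_core import (
    ElementalFormula,
    MetaboliteSpec,
    ModelSpec,
    ReactionSpec,
    clamp_bound,
)

_NS = "https://commgem.invalid/ns/1"
_UNITS_ID = "mmol_per_gDW_per_hr"


def _check(ret, what: str) -> None:
    if ret not in (None, libsbml.LIBSBML_OPERATION_SUCCESS):
        raise FormatError(f"libsbml call failed while writing {what}: code {ret}")


def _strip_outer_parens(expr: str) -> str:
    expr = expr.strip()
    while expr.startswith("(") and expr.endswith(")"):
        depth = 0
        for i, ch in enumerate(expr):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth == 0 and i < len(expr) - 1:
                    return expr
        expr = expr[1:-1].strip()
    return expr


def _add_cv_terms(element, annotations: dict) -> None:
    if not annotations:
        return
    element.setMetaId("meta_" + element.getId())
    cv = libsbml.CVTerm(libsbml.BIOLOGICAL_QUALIFIER)
    cv.setBiologicalQualifierType(libsbml.BQB_IS)
    for db in sorted(annotations):
        for acc in sorted(annotations[db]):
            cv.addResource(f"https://identifiers.org/{db}/{acc}")
    _check(element.addCVTerm(cv), "annotation")


def _read_cv_terms(element) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for i in range(element.getNumCVTerms()):
        term = element.getCVTerm(i)
        for j in range(term.getNumResources()):
            uri = term.getResourceURI(j)
            rest = None
            for prefix in ("https://identifiers.org/", "http://identifiers.org/"):
                if uri.startswith(prefix):
                    rest = uri[len(prefix):]
                    break
            if rest is None:
                continue
            if "/" in rest:
                db, acc = rest.split("/", 1)
            elif ":" in rest:
                db, acc = rest.split(":", 1)
            else:
                continue
            out.setdefault(db, set()).add(acc)
    return out


def write_sbml(model: ModelSpec, path: str) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel(model.id)
    if model.name:
        sm.setName(model.name)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    # flux units (mmol per gram dry weight per hour)
    udef = sm.createUnitDefinition()
    udef.setId(_UNITS_ID)
    for kind, exp, scale, mult in (
        (libsbml.UNIT_KIND_MOLE, 1, -3, 1.0),
        (libsbml.UNIT_KIND_GRAM, -1, 0, 1.0),
        (libsbml.UNIT_KIND_SECOND, -1, 0, 3600.0),
    ):
        u = udef.createUnit()
        u.setKind(kind)
        u.setExponent(exp)
        u.setScale(scale)
        u.setMultiplier(mult)

    for cid, cname in model.compartments.items():
        comp = sm.createCompartment()
        _check(comp.setId(cid), f"compartment {cid}")
        if cname:
            comp.setName(cname)
        comp.setConstant(True)
        comp.setSize(1.0)

    for met in model.metabolites:
        sp = sm.createSpecies()
        _check(sp.setId(met.id), f"species {met.id}")
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(met.compartment_id)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(met.formula.to_string())
        if met.charge is not None:
            splug.setCharge(int(met.charge))
        _add_cv_terms(sp, met.annotations)

    for gene in model.genes:
        gp = mplug.createGeneProduct()
        _check(gp.setId(gene), f"gene {gene}")
        gp.setLabel(gene)

    shared = {0.0: "bound_zero", DEFAULT_BOUND: "bound_default_upper",
              -DEFAULT_BOUND: "bound_default_lower"}
    made_params: set[str] = set()

    def bound_param(value: float, rid: str, which: str) -> str:
        pid = shared.get(value, f"{rid}_{which}_bound")
        if pid not in made_params:
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            par.setUnits(_UNITS_ID)
            made_params.add(pid)
        return pid

    for rxn in model.reactions:
        sr = sm.createReaction()
        _check(sr.setId(rxn.id), f"reaction {rxn.id}")
        if rxn.name:
            sr.setName(rxn.name)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                ref = sr.createReactant()
            else:
                ref = sr.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound, rxn.id, "lower"))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound, rxn.id, "upper"))
        if rxn.gene_association:
            gpa = rplug.createGeneProductAssociation()
            ret = gpa.setAssociation(rxn.gene_association)
            _check(ret, f"gene association of {rxn.id}")
        _add_cv_terms(sr, rxn.annotations)

    if model.objective is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize" if model.objective[1] == "max" else "minimize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective[0])
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if model.meta:
        sm.setMetaId("meta_" + model.id)
        payload = escape(json.dumps(model.meta, sort_keys=True))
        _check(
            sm.appendAnnotation(f'<commgem xmlns="{_NS}">{payload}</commgem>'),
            "model metadata",
        )

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise FormatError(f"could not write SBML to {path}")


def read_sbml(path: str) -> ModelSpec:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_FATAL) or doc.getNumErrors(
        libsbml.LIBSBML_SEV_ERROR
    ):
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR) or doc.getError(0)
        raise FormatError(f"SBML parse failure in {path}: {err.getMessage().strip()}")
    sm = doc.getModel()
    if sm is None:
        raise FormatError(f"{path} contains no SBML model")
    mplug = sm.getPlugin("fbc")

    compartments = {
        sm.getCompartment(i).getId(): sm.getCompartment(i).getName()
        for i in range(sm.getNumCompartments())
    }

    metabolites = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = ElementalFormula.from_string(splug.getChemicalFormula())
                if formula is None:
                    formula = ElementalFormula()  # unparseable → unknown
            if splug.isSetCharge():
                charge = splug.getCharge()
        metabolites.append(
            MetaboliteSpec(
                id=sp.getId(),
                name=sp.getName(),
                compartment_id=sp.getCompartment(),
                formula=formula,
                charge=charge,
                annotations=_read_cv_terms(sp),
            )
        )

    genes = []
    if mplug is not None:
        genes = [
            mplug.getGeneProduct(i).getId() for i in range(mplug.getNumGeneProducts())
        ]

    def param_value(pid: str, rid: str, which: str) -> float:
        par = sm.getParameter(pid)
        if par is None:
            raise FormatError(f"reaction {rid} references missing parameter {pid!r}")
        return clamp_bound(par.getValue(), which, rid)

    reactions = []
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        if rplug is None or not rplug.isSetLowerFluxBound():
            raise FormatError(f"reaction {sr.getId()} lacks FBC flux bounds")
        lb = param_value(rplug.getLowerFluxBound(), sr.getId(), "lower")
        ub = param_value(rplug.getUpperFluxBound(), sr.getId(), "upper")
        gpr = None
        gpa = rplug.getGeneProductAssociation()
        if gpa is not None and gpa.getAssociation() is not None:
            gpr = _strip_outer_parens(
                libsbml.FbcAssociation.toInfix(gpa.getAssociation())
            )
        reactions.append(
            ReactionSpec(
                id=sr.getId(),
                name=sr.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_association=gpr,
                annotations=_read_cv_terms(sr),
            )
        )

    objective = None
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(mplug.getActiveObjectiveId()) or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            direction = "max" if obj.getType() == "maximize" else "min"
            objective = (obj.getFluxObjective(0).getReaction(), direction)

    meta: dict = {}
    ann = sm.getAnnotation()
    if ann is not None:
        for i in range(ann.getNumChildren()):
            child = ann.getChild(i)
            if child.getName() == "commgem" and child.getURI() == _NS:
                meta = json.loads(child.getChild(0).getCharacters())

    return ModelSpec(
        id=sm.getId() or "model",
        name=sm.getName(),
        compartments=compartments,
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective=objective,
        meta=meta,
    )


def validate_sbml(path: str) -> list[str]:
    """Run libsbml's full consistency check; return error-level messages."""
    doc = libsbml.readSBMLFromFile(str(path))
    doc.checkConsistency()
    errors = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            errors.append(err.getMessage().strip())
    return errors
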