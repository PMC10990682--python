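"""JSON model dialect mirroring :class:`~commgem.model_core.ModelSpec`."""

from __future__ import annotations

import json

from .errors import FormatError, IntegrityError
from .model_core import ElementalFormula, MetaboliteSpec, ModelSpec, ReactionSpec

_SCHEMA = "commgem-model-1"


def model_to_dict(model: ModelSpec) -> dict:
    return {
        "schema": _SCHEMA,
        "id": model.id,
        "name": model.name,
        "compartments": dict(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment_id,
                "formula": m.formula.to_string() if m.formula is not None else None,
                "charge": m.charge,
                "annotations": {k: sorted(v) for k, v in sorted(m.annotations.items())},
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_association": r.gene_association,
                "annotations": {k: sorted(v) for k, v in sorted(r.annotations.items())},
            }
            for r in model.reactions
        ],
        "genes": list(model.genes),
        "objective": list(model.objective) if model.objective else None,
        "meta": model.meta,
    }


def model_from_dict(data: dict) -> ModelSpec:
    try:
        metabolites = [
            MetaboliteSpec(
                id=m["id"],
                name=m.get("name", ""),
                compartment_id=m["compartment"],
                formula=(
                    ElementalFormula.from_string(m["formula"])
                    if m.get("formula") is not None
                    else None
                ),
                charge=m.get("charge"),
                annotations={k: set(v) for k, v in m.get("annotations", {}).items()},
            )
            for m in data["metabolites"]
        ]
        reactions = [
            ReactionSpec(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gene_association=r.get("gene_association"),
                annotations={k: set(v) for k, v in r.get("annotations", {}).items()},
            )
            for r in data["reactions"]
        ]
        objective = tuple(data["objective"]) if data.get("objective") else None
        return ModelSpec(
            id=data["id"],
            name=data.get("name", ""),
            compartments=dict(data["compartments"]),
            metabolites=metabolites,
            reactions=reactions,
            genes=list(data.get("genes", [])),
            objective=objective,
            meta=data.get("meta", {}),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed JSON model: {exc!r}") from exc


def write_json(model: ModelSpec, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=False)
        fh.write("\n")


def read_json(path: str) -> ModelSpec:
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {path}: {exc}") from exc
    if not isinstance(data, dict) or data.get("schema") != _SCHEMA:
        raise FormatError(f"{path} is not a {_SCHEMA} document")
    model = model_from_dict(data)
    try:
        model.validate()
    except IntegrityError:
        raise
    return model
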