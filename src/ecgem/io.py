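"""Model readers/writers: SBML Level 3 + FBC v2 (via libsbml) and a COBRA-style
JSON dialect.

Both formats round-trip the full model structure: stoichiometry, bounds, GPR
rules, subsystems, objective.  Flux bounds are stored as SBML parameters, GPRs
as ``fbc:geneProductAssociation`` trees, subsystems in the reaction notes (the
same convention cobrapy uses).
"""

from __future__ import annotations

import json
import math
import os
import re

import libsbml

from .model import MetabolicModel, Metabolite, Reaction

__all__ = ["read_model", "write_model", "read_json", "write_json", "read_sbml", "write_sbml"]

_BOUND_INF = 1e6  # stand-in for +/- infinity inside SBML parameter values


class ModelFormatError(ValueError):
    """Raised when a model file does not parse under the named standard."""


def _format_from_path(path: str, fmt: str | None) -> str:
    if fmt:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext == ".json":
        return "json"
    if ext in (".xml", ".sbml"):
        return "sbml-fbc"
    raise ModelFormatError(f"cannot infer model format from path {path!r}")


def read_model(path: str, format: str | None = None) -> MetabolicModel:
    """Read a model from SBML-FBC or JSON; the format is inferred from the
    extension when not given."""
    fmt = _format_from_path(path, format)
    if fmt == "json":
        return read_json(path)
    if fmt in ("sbml", "sbml-fbc"):
        return read_sbml(path)
    raise ModelFormatError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str, format: str | None = None) -> None:
    fmt = _format_from_path(path, format)
    if fmt == "json":
        write_json(model, path)
    elif fmt in ("sbml", "sbml-fbc"):
        write_sbml(model, path)
    else:
        raise ModelFormatError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# JSON dialect (mirrors the common COBRA JSON field layout)
# ---------------------------------------------------------------------------


def write_json(model: MetabolicModel, path: str) -> None:
    model.validate()
    doc = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gene_rule,
                "subsystem": r.subsystem,
                "objective_coefficient": 1.0
                if r.id == model.objective_reaction_id
                else 0.0,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in model.genes],
        "annotations": _jsonable_annotations(model.annotations),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)


def _jsonable_annotations(ann: dict) -> dict:
    try:
        json.dumps(ann)
        return ann
    except TypeError:
        return {}


def read_json(path: str) -> MetabolicModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON ({exc})") from exc
    model = MetabolicModel(id=doc.get("id", "model"))
    for m in doc.get("metabolites", []):
        if "id" not in m:
            raise ModelFormatError(f"{path}: metabolite entry without id: {m}")
        model.metabolites.append(
            Metabolite(id=m["id"], name=m.get("name", ""), compartment=m.get("compartment", ""))
        )
    objective = None
    for r in doc.get("reactions", []):
        if "id" not in r:
            raise ModelFormatError(f"{path}: reaction entry without id: {r}")
        model.reactions.append(
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r.get("metabolites", {}).items()},
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                gene_rule=r.get("gene_reaction_rule", ""),
                subsystem=r.get("subsystem", ""),
                name=r.get("name", ""),
            )
        )
        if r.get("objective_coefficient", 0.0):
            objective = r["id"]
    model.genes = [g["id"] for g in doc.get("genes", [])]
    if objective is None:
        raise ModelFormatError(f"{path}: no reaction carries a non-zero objective coefficient")
    model.objective_reaction_id = objective
    model.annotations = doc.get("annotations", {})
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC v2
# ---------------------------------------------------------------------------

_SBML_ID_FIX = re.compile(r"[^A-Za-z0-9_]")


def _sid(prefix: str, raw: str) -> str:
    """SBML SIds must match [A-Za-z_][A-Za-z0-9_]*; prefix and sanitize."""
    return prefix + _SBML_ID_FIX.sub("__", raw)


def write_sbml(model: MetabolicModel, path: str) -> None:
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_SBML_ID_FIX.sub("_", model.id) or "model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment or "c" for m in model.metabolites}) or ["c"]
    for cid in compartments:
        comp = sm.createCompartment()
        comp.setId(_sid("", cid))
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(_sid("M_", m.id))
        sp.setName(m.name or m.id)
        sp.setCompartment(_sid("", m.compartment or "c"))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    genes = sorted(set(model.genes) | {g for r in model.reactions for g in r.genes()})
    for g in genes:
        gp = mplug.createGeneProduct()
        gp.setId(_sid("G_", g))
        gp.setLabel(g)

    # unique bound parameters per reaction keep the writer simple and lossless
    def add_param(pid: str, value: float) -> str:
        p = sm.createParameter()
        p.setId(pid)
        if math.isinf(value):
            value = math.copysign(_BOUND_INF, value)
        p.setValue(value)
        p.setConstant(True)
        return pid

    for r in model.reactions:
        rx = sm.createReaction()
        rid = _sid("R_", r.id)
        rx.setId(rid)
        rx.setName(r.name or r.id)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        if r.subsystem:
            rx.setNotes(
                f"<body xmlns=\"http://www.w3.org/1999/xhtml\"><p>SUBSYSTEM: {r.subsystem}</p></body>"
            )
        for mid, coef in r.stoichiometry.items():
            if coef < 0:
                sr = rx.createReactant()
                sr.setStoichiometry(-coef)
            else:
                sr = rx.createProduct()
                sr.setStoichiometry(coef)
            sr.setSpecies(_sid("M_", mid))
            sr.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(add_param(f"{rid}_lb", r.lower_bound))
        rplug.setUpperFluxBound(add_param(f"{rid}_ub", r.upper_bound))
        if r.gene_rule:
            gpa = rplug.createGeneProductAssociation()
            # libsbml matches existing gene products by label, so pass the
            # rule with the raw gene names
            gpa.setAssociation(r.gene_rule)

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(_sid("R_", model.objective_reaction_id))
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise IOError(f"could not write SBML to {path}")


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def read_sbml(path: str) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(f"{path}: SBML parse error: {err.getMessage().strip()}")
    sm = doc.getModel()
    if sm is None:
        raise ModelFormatError(f"{path}: file contains no SBML model element")
    mplug = sm.getPlugin("fbc")
    if mplug is None:
        raise ModelFormatError(f"{path}: model lacks the FBC package (no flux bounds/objective)")

    model = MetabolicModel(id=sm.getId() or "model")
    gp_label = {}
    for i in range(mplug.getNumGeneProducts()):
        gp = mplug.getGeneProduct(i)
        gp_label[gp.getId()] = gp.getLabel() or _strip_prefix(gp.getId(), "G_")
    model.genes = sorted(gp_label.values())

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        model.metabolites.append(
            Metabolite(
                id=_strip_prefix(sp.getId(), "M_"),
                name=sp.getName(),
                compartment=sp.getCompartment(),
            )
        )

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    for i in range(sm.getNumReactions()):
        rx = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            mid = _strip_prefix(sr.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            mid = _strip_prefix(sr.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + sr.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        if rplug is None or not rplug.isSetLowerFluxBound():
            raise ModelFormatError(f"{path}: reaction {rx.getId()} lacks FBC flux bounds")
        lb = params[rplug.getLowerFluxBound()]
        ub = params[rplug.getUpperFluxBound()]
        rule = ""
        if rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            rule = _association_to_rule(assoc, gp_label)
        subsystem = ""
        if rx.isSetNotes():
            m = re.search(r"SUBSYSTEM:\s*([^<]+)", rx.getNotesString())
            if m:
                subsystem = m.group(1).strip()
        model.reactions.append(
            Reaction(
                id=_strip_prefix(rx.getId(), "R_"),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=rule,
                subsystem=subsystem,
                name=rx.getName(),
            )
        )

    objective = None
    active = mplug.getActiveObjective()
    if active is not None and active.getNumFluxObjectives() > 0:
        objective = _strip_prefix(active.getFluxObjective(0).getReaction(), "R_")
    if objective is None:
        raise ModelFormatError(f"{path}: no active FBC objective defined")
    model.objective_reaction_id = objective
    model.validate()
    return model


def _association_to_rule(assoc, gp_label: dict[str, str]) -> str:
    if assoc is None:
        return ""
    code = assoc.getTypeCode()
    if code == libsbml.SBML_FBC_GENEPRODUCTREF:
        return gp_label.get(assoc.getGeneProduct(), assoc.getGeneProduct())
    if code == libsbml.SBML_FBC_AND:
        parts = [
            _association_to_rule(assoc.getAssociation(i), gp_label)
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " and ".join(parts) + ")"
    if code == libsbml.SBML_FBC_OR:
        parts = [
            _association_to_rule(assoc.getAssociation(i), gp_label)
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " or ".join(parts) + ")"
    raise ModelFormatError(f"unsupported gene association element (type code {code})")
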