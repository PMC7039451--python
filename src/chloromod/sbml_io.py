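"""SBML reading and writing for organelle modules.

Writes SBML Level 3 Version 1 with the ``fbc`` (v2) package: flux bounds as
fbc parameters, GPRs as fbc gene-product associations, the objective as an
fbc objective.  Reads both L3+fbc and the older Level 2 COBRA dialect
(bounds in kinetic-law parameters, GPR/subsystem in notes fields).

SBML SIds cannot contain ``@``, so organism-tag prefixes are escaped with
the COBRA-style character code ``__64__`` (and decoded on read); reactions,
species and genes carry the conventional ``R_`` / ``M_`` / ``G_`` prefixes.
Module-specific state with no SBML representation (default bounds, organism
registry, mode registry, subsystems, KEGG ids) rides in structured notes.
"""

from __future__ import annotations

import logging
from typing import Optional

import libsbml

from .gpr import GPRRule
from .model import ModeEntry, OrganelleModule, Reaction

__all__ = ["read_sbml", "write_sbml", "SBMLReadError", "SBMLWriteError"]

logger = logging.getLogger(__name__)


class SBMLReadError(ValueError):
    pass


class SBMLWriteError(ValueError):
    pass


def _encode_sid(raw: str, prefix: str) -> str:
    return prefix + raw.replace("@", "__64__")


def _decode_sid(sid: str, prefix: str) -> str:
    if sid.startswith(prefix):
        sid = sid[len(prefix):]
    return sid.replace("__64__", "@")


def _notes_from_pairs(pairs: dict) -> str:
    body = "".join(
        f"<p>{key}: {value}</p>" for key, value in pairs.items() if value not in (None, "")
    )
    return (
        '<body xmlns="http://www.w3.org/1999/xhtml">' + body + "</body>"
    )


def _pairs_from_notes(node) -> dict:
    out: dict = {}
    if node is None:
        return out
    text = node.toXMLString()
    # notes are flat <p>KEY: value</p> lines (COBRA convention)
    import re

    for m in re.finditer(r"<p>\s*([^:<]+):\s*([^<]*)</p>", text):
        out[m.group(1).strip()] = m.group(2).strip()
    return out


# -- writing ---------------------------------------------------------------


def _gpr_root_to_fbc(rule, fbc_rxn):
    """Translate a GPR tree into an fbc gene-product association."""
    root = rule._root

    def fill(node, container):
        for child in node.children:
            if child.op == "gene":
                ref = container.createGeneProductRef()
                ref.setGeneProduct(_encode_sid(child.gene, "G_"))
            elif child.op == "and":
                fill(child, container.createAnd())
            else:
                fill(child, container.createOr())

    gpa = fbc_rxn.createGeneProductAssociation()
    if root.op == "gene":
        ref = gpa.createGeneProductRef()
        ref.setGeneProduct(_encode_sid(root.gene, "G_"))
    elif root.op == "and":
        fill(root, gpa.createAnd())
    else:
        fill(root, gpa.createOr())


def write_sbml(model: OrganelleModule, path: str) -> None:
    """Serialize *model* as SBML L3V1 + fbc v2.

    Round trip: ``read_sbml(write_sbml(m))`` preserves the S-matrix, bounds,
    default bounds, tags, GPRs, subsystems, KEGG ids, objective and mode
    registry.
    """
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb = doc.createModel()
    sb.setId(_encode_sid(model.id, "") or "model")
    sb.setName(model.name)
    mplug = sb.getPlugin("fbc")
    mplug.setStrict(False)

    model_notes = {
        "ORGANISMS": ",".join(sorted(model.organisms)),
        "ACTIVE_MODE": model.active_mode or "",
        "MODE_REGISTRY": ";".join(
            f"{org}={entry.biomass_id}" for org, entry in sorted(model.mode_registry.items())
        ),
        "IS_FUSED": "true" if model.is_fused else "",
    }
    sb.setNotes(_notes_from_pairs(model_notes))

    for cid, cname in model.compartments.items():
        comp = sb.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sb.createSpecies()
        sp.setId(_encode_sid(met.id, "M_"))
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.charge is not None:
            splug.setCharge(int(met.charge))
        if met.formula:
            splug.setChemicalFormula(met.formula)
        if met.kegg_id:
            sp.setNotes(_notes_from_pairs({"KEGG": met.kegg_id}))

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_encode_sid(gene, "G_"))
        gp.setLabel(gene)

    bound_params: dict = {}

    def bound_param(value: float) -> str:
        key = float(value)
        if key not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sb.createParameter()
            par.setId(pid)
            par.setValue(key)
            par.setConstant(True)
            bound_params[key] = pid
        return bound_params[key]

    for rxn in model.reactions:
        rx = sb.createReaction()
        rx.setId(_encode_sid(rxn.id, "R_"))
        rx.setName(rxn.name or rxn.id)
        rx.setFast(False)
        rx.setReversible(rxn.lower_bound < 0)
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                ref = rx.createReactant()
            else:
                ref = rx.createProduct()
            ref.setSpecies(_encode_sid(met_id, "M_"))
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr:
            _gpr_root_to_fbc(rxn.gpr, rplug)
        notes = {
            "DEFAULT_BOUNDS": f"{rxn.default_bounds[0]},{rxn.default_bounds[1]}",
            "SUBSYSTEM": "; ".join(rxn.subsystems),
            "BIOMASS_ORGANISM": rxn.biomass_organism or "",
            "IS_BIOMASS": "true" if rxn.is_biomass else "",
        }
        rx.setNotes(_notes_from_pairs(notes))

    if model.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize" if model.objective_direction == "max" else "minimize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction(_encode_sid(model.objective_id, "R_"))
        fo.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise SBMLWriteError(f"could not write SBML to {path!r}")


# -- reading ---------------------------------------------------------------


def _fbc_assoc_to_gpr(assoc) -> str:
    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        return _decode_sid(assoc.getGeneProduct(), "G_")
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_fbc_assoc_to_gpr(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_fbc_assoc_to_gpr(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    return ""


def _kegg_from_species(sp) -> Optional[str]:
    pairs = _pairs_from_notes(sp.getNotes())
    if "KEGG" in pairs:
        return pairs["KEGG"] or None
    # identifiers.org annotations (CVTerms)
    for i in range(sp.getNumCVTerms()):
        term = sp.getCVTerm(i)
        for j in range(term.getNumResources()):
            uri = term.getResourceURI(j)
            if "kegg.compound" in uri:
                return uri.rstrip("/").rsplit("/", 1)[-1].rsplit(":", 1)[-1]
    return None


def read_sbml(path: str) -> OrganelleModule:
    """Parse an SBML file into an :class:`OrganelleModule`.

    Supports L3+fbc and L2 with COBRA notes/kinetic-law bounds.  Missing
    bounds default to (-1000, 1000) for reversible reactions and (0, 1000)
    otherwise, with a logged warning.  A reaction referencing an undeclared
    species is an error naming the species.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_FATAL) or doc.getModel() is None:
        raise SBMLReadError(
            f"{path}: not well-formed SBML "
            f"({doc.getError(0).getMessage().strip() if doc.getNumErrors() else 'no model element'})"
        )
    level = doc.getLevel()
    if level < 2:
        raise SBMLReadError(f"{path}: unsupported SBML level {level} (need level 2 or 3)")
    sb = doc.getModel()
    mplug = sb.getPlugin("fbc")

    model_pairs = _pairs_from_notes(sb.getNotes())
    organisms = [s for s in model_pairs.get("ORGANISMS", "").split(",") if s]
    model = OrganelleModule(
        id=sb.getId() or "model",
        name=sb.getName() or sb.getId(),
        compartments={
            sb.getCompartment(i).getId(): sb.getCompartment(i).getName() or sb.getCompartment(i).getId()
            for i in range(sb.getNumCompartments())
        },
        organisms=organisms or None,
    )
    model.is_fused = model_pairs.get("IS_FUSED", "") == "true"

    declared: dict = {}
    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        met_id = _decode_sid(sp.getId(), "M_")
        declared[sp.getId()] = met_id
        kwargs = {}
        splug = sp.getPlugin("fbc")
        if splug is not None and splug.isSetCharge():
            kwargs["charge"] = splug.getCharge()
        if splug is not None and splug.isSetChemicalFormula():
            kwargs["formula"] = splug.getChemicalFormula()
        model.new_metabolite(
            met_id,
            name=sp.getName() or met_id,
            compartment=sp.getCompartment() or "c",
            kegg_id=_kegg_from_species(sp),
            **kwargs,
        )

    params = {
        sb.getParameter(i).getId(): sb.getParameter(i).getValue()
        for i in range(sb.getNumParameters())
    }

    for i in range(sb.getNumReactions()):
        rx = sb.getReaction(i)
        rxn_id = _decode_sid(rx.getId(), "R_")
        stoich: dict = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            if ref.getSpecies() not in declared:
                raise SBMLReadError(
                    f"{path}: reaction {rx.getId()!r} references undeclared species "
                    f"{ref.getSpecies()!r}"
                )
            stoich[declared[ref.getSpecies()]] = stoich.get(declared[ref.getSpecies()], 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            if ref.getSpecies() not in declared:
                raise SBMLReadError(
                    f"{path}: reaction {rx.getId()!r} references undeclared species "
                    f"{ref.getSpecies()!r}"
                )
            stoich[declared[ref.getSpecies()]] = stoich.get(declared[ref.getSpecies()], 0.0) + ref.getStoichiometry()

        pairs = _pairs_from_notes(rx.getNotes())
        lb = ub = None
        gpr_text = ""
        rplug = rx.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            lb = params.get(rplug.getLowerFluxBound())
            ub = params.get(rplug.getUpperFluxBound())
            if rplug.isSetGeneProductAssociation():
                gpr_text = _fbc_assoc_to_gpr(rplug.getGeneProductAssociation().getAssociation())
        if lb is None and rx.isSetKineticLaw():
            # L2 COBRA dialect
            kl = rx.getKineticLaw()
            for j in range(kl.getNumParameters()):
                par = kl.getParameter(j)
                if par.getId() == "LOWER_BOUND":
                    lb = par.getValue()
                elif par.getId() == "UPPER_BOUND":
                    ub = par.getValue()
        if not gpr_text:
            gpr_text = pairs.get("GENE_ASSOCIATION", "") or pairs.get("GENE ASSOCIATION", "")
        if lb is None or ub is None:
            rev = rx.getReversible()
            lb = -1000.0 if rev else 0.0 if lb is None else lb
            ub = 1000.0 if ub is None else ub
            logger.warning(
                "reaction %s has no explicit bounds; defaulting to (%s, %s)",
                rxn_id, lb, ub,
            )
        subsystems = [
            s.strip()
            for s in (pairs.get("SUBSYSTEM", "") or "").split(";")
            if s.strip()
        ]
        default_bounds = None
        if "DEFAULT_BOUNDS" in pairs:
            try:
                dlo, dhi = pairs["DEFAULT_BOUNDS"].split(",")
                default_bounds = (float(dlo), float(dhi))
            except ValueError:
                default_bounds = None
        model.add_reaction(
            Reaction(
                id=rxn_id,
                name=rx.getName() or rxn_id,
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                default_bounds=default_bounds,
                gpr=GPRRule.from_string(gpr_text),
                subsystems=subsystems,
                is_biomass=pairs.get("IS_BIOMASS", "") == "true",
                biomass_organism=pairs.get("BIOMASS_ORGANISM") or None,
            )
        )

    for entry in (model_pairs.get("MODE_REGISTRY", "") or "").split(";"):
        if not entry:
            continue
        org, _, biomass_id = entry.partition("=")
        if model.has_reaction(biomass_id):
            model.mode_registry[org] = ModeEntry(biomass_id=biomass_id)
            model.organisms.add(org)
    model.active_mode = model_pairs.get("ACTIVE_MODE") or None

    # objective
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            fo = obj.getFluxObjective(0)
            rid = _decode_sid(fo.getReaction(), "R_")
            if model.has_reaction(rid):
                model.objective_id = rid
                model.objective_direction = (
                    "min" if obj.getType() == "minimize" else "max"
                )
    else:
        # L2 COBRA objective coefficient
        for i in range(sb.getNumReactions()):
            rx = sb.getReaction(i)
            if rx.isSetKineticLaw():
                kl = rx.getKineticLaw()
                for j in range(kl.getNumParameters()):
                    par = kl.getParameter(j)
                    if par.getId() == "OBJECTIVE_COEFFICIENT" and par.getValue() != 0:
                        model.objective_id = _decode_sid(rx.getId(), "R_")
                        model.objective_direction = "max"
    return model
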