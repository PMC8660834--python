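"""SBML Level 3 + FBC v2 reading and writing, plus tabular model export.

The reconstruction exchange format is SBML Level 3 Version 1 with the
Flux Balance Constraints (FBC) version 2 package: flux bounds are stored
as FBC parameters, gene rules as FBC gene-product associations and the
objective as the active FBC objective.  Species formulas and charges are
stored through FBC; a non-integer charge (permitted for pooled
pseudo-species) falls back to a notes entry since FBC only allows
integer charges.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Dict, List, Optional, Union

import libsbml
import pandas as pd

from .model import (DEFAULT_UB, MetabolicModel, Metabolite, Reaction,
                    format_formula, genes_in_rule, parse_formula)

__all__ = ["read_sbml", "write_sbml", "write_tsv", "SBMLError"]


class SBMLError(RuntimeError):
    """Raised for malformed SBML input or inconsistent models."""


_SID_SAFE = re.compile(r"[^A-Za-z0-9_]")


def _sid(prefix: str, raw: str) -> str:
    """Sanitize an identifier into a valid SBML SId with a type prefix."""
    clean = _SID_SAFE.sub("_", raw)
    if not clean or clean[0].isdigit():
        clean = "_" + clean
    return prefix + clean


def _notes(pairs: Dict[str, str]) -> str:
    body = "".join(
        f"<p>{k}: {v}</p>" for k, v in pairs.items() if v not in ("", None))
    return (f'<notes><body xmlns="http://www.w3.org/1999/xhtml">{body}'
            "</body></notes>")


def _parse_notes(node) -> Dict[str, str]:
    out: Dict[str, str] = {}
    if node is None or not node.isSetNotes():
        return out
    text = node.getNotesString()
    for match in re.finditer(r"<p>\s*([^<:]+?)\s*:\s*(.*?)\s*</p>", text,
                             re.DOTALL):
        out[match.group(1)] = match.group(2)
    return out


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_sbml(model: MetabolicModel, path: Union[str, Path]) -> None:
    """Serialize a model to SBML L3V1 + FBC v2.

    All typed fields (ids, names, compartments, formulas, charges, bounds,
    gene rules, subsystems, EC numbers, exchange flags, objective) survive a
    round trip through :func:`read_sbml`.  Unresolvable references abort
    before any file is written.
    """
    model.validate()

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sid("", model.id))
    sm.setName(model.name)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted({m.compartment for m in model.metabolites.values()}):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    gene_sid: Dict[str, str] = {}
    for gene in sorted(model.gene_ids):
        gp = mplug.createGeneProduct()
        sid = _sid("G_", gene)
        gp.setId(sid)
        gp.setLabel(gene)
        gene_sid[gene] = sid

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_sid("M_", met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialConcentration(0.0)
        splug = sp.getPlugin("fbc")
        notes = {"ORIGINAL_ID": met.id}
        if met.formula:
            # FBC only allows integer subscripts; pooled pseudo-species
            # with fractional formulas go into the notes instead
            if all(float(n).is_integer() for n in met.formula.values()):
                splug.setChemicalFormula(format_formula(met.formula))
            else:
                notes["FORMULA"] = format_formula(met.formula)
        if float(met.charge).is_integer():
            splug.setCharge(int(met.charge))
        else:
            notes["CHARGE"] = repr(met.charge)
        sp.setNotes(_notes(notes))

    def bound_param(value: float, tag: str) -> str:
        pid = _sid("", tag)
        par = sm.createParameter()
        par.setId(pid)
        par.setValue(value)
        par.setConstant(True)
        par.setSBOTerm("SBO:0000625")
        return pid

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        rid = _sid("R_", rxn.id)
        sr.setId(rid)
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(_sid("M_", met_id))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound, f"{rid}_lb"))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound, f"{rid}_ub"))
        if rxn.gene_rule:
            infix = rxn.gene_rule
            for gene in sorted(genes_in_rule(rxn.gene_rule), key=len,
                               reverse=True):
                infix = re.sub(rf"(?<![\w.\-]){re.escape(gene)}(?![\w.\-])",
                               gene_sid[gene], infix)
            gpa = rplug.createGeneProductAssociation()
            if gpa.setAssociation(infix, True, False) != libsbml.LIBSBML_OPERATION_SUCCESS:
                raise SBMLError(f"cannot encode gene rule of {rxn.id!r}: "
                                f"{rxn.gene_rule!r}")
        sr.setNotes(_notes({
            "ORIGINAL_ID": rxn.id,
            "SUBSYSTEM": rxn.subsystem,
            "EC_NUMBERS": ",".join(rxn.ec_numbers),
            "IS_EXCHANGE": "true" if rxn.is_exchange else "",
        }))

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    if model.objective_id is not None:
        fo = objective.createFluxObjective()
        fo.setReaction(_sid("R_", model.objective_id))
        fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise SBMLError(f"failed to write SBML to {path}")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_sbml(path: Union[str, Path]) -> MetabolicModel:
    """Load an SBML Level 3 + FBC model.

    Identifiers, bounds, gene rules, formulas and charges are preserved
    where annotated; the objective is taken from the active FBC objective.
    Malformed XML raises :class:`SBMLError`; a reaction without FBC flux
    bounds raises an error naming the reaction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [doc.getError(i).getMessage()
                for i in range(doc.getNumErrors())
                if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR]
        raise SBMLError(f"malformed SBML in {path}: {msgs[0].strip()}")
    sm = doc.getModel()
    if sm is None:
        raise SBMLError(f"no model element in {path}")
    mplug = sm.getPlugin("fbc")

    gene_by_sid: Dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_by_sid[gp.getId()] = gp.getLabel() or gp.getId()

    def strip(prefix: str, sid: str, notes: Dict[str, str]) -> str:
        if "ORIGINAL_ID" in notes:
            return notes["ORIGINAL_ID"]
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    metabolites: List[Metabolite] = []
    sid_to_met: Dict[str, str] = {}
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        notes = _parse_notes(sp)
        splug = sp.getPlugin("fbc")
        formula: Dict[str, float] = {}
        charge = 0.0
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = parse_formula(splug.getChemicalFormula())
            if splug.isSetCharge():
                charge = float(splug.getCharge())
        if "FORMULA" in notes:
            formula = parse_formula(notes["FORMULA"])
        if "CHARGE" in notes:
            charge = float(notes["CHARGE"])
        met_id = strip("M_", sp.getId(), notes)
        sid_to_met[sp.getId()] = met_id
        metabolites.append(Metabolite(
            id=met_id, name=sp.getName() or met_id,
            compartment=sp.getCompartment() or "c",
            formula=formula, charge=charge))

    reactions: List[Reaction] = []
    sid_to_rxn: Dict[str, str] = {}
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        notes = _parse_notes(sr)
        rxn_id = strip("R_", sr.getId(), notes)
        sid_to_rxn[sr.getId()] = rxn_id
        stoich: Dict[str, float] = {}
        for k in range(sr.getNumReactants()):
            ref = sr.getReactant(k)
            met = sid_to_met[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for k in range(sr.getNumProducts()):
            ref = sr.getProduct(k)
            met = sid_to_met[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}

        rplug = sr.getPlugin("fbc")
        if rplug is None or not (rplug.isSetLowerFluxBound()
                                 and rplug.isSetUpperFluxBound()):
            raise SBMLError(
                f"reaction {rxn_id!r} lacks FBC flux bounds in {path}")
        lb_par = sm.getParameter(rplug.getLowerFluxBound())
        ub_par = sm.getParameter(rplug.getUpperFluxBound())
        if lb_par is None or ub_par is None:
            raise SBMLError(
                f"reaction {rxn_id!r}: unresolved flux-bound parameter")
        lb, ub = lb_par.getValue(), ub_par.getValue()
        lb = -DEFAULT_UB if math.isinf(lb) else lb
        ub = DEFAULT_UB if math.isinf(ub) else ub

        gene_rule = ""
        if rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                gene_rule = assoc.toInfix()
                # toInfix emits labels; normalize parentheses spacing only.
                gene_rule = re.sub(r"\s+", " ", gene_rule).strip()

        ec = [e for e in notes.get("EC_NUMBERS", "").split(",") if e]
        reactions.append(Reaction(
            id=rxn_id, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            gene_rule=gene_rule, name=sr.getName() or rxn_id,
            subsystem=notes.get("SUBSYSTEM", ""), ec_numbers=ec,
            is_exchange=notes.get("IS_EXCHANGE", "") == "true"))

    model = MetabolicModel(sm.getId() or path.stem,
                           metabolites, reactions,
                           name=sm.getName() or sm.getId())

    # Structural exchange detection for files from other tools.
    met_comp = {m.id: m.compartment for m in metabolites}
    for rxn in model.reactions.values():
        if not rxn.is_exchange and len(rxn.stoichiometry) == 1:
            (met_id,) = rxn.stoichiometry
            if met_comp[met_id] == "e" and rxn.id.startswith("EX_"):
                rxn.is_exchange = True

    if mplug is not None:
        obj = mplug.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_id = sid_to_rxn.get(
                obj.getFluxObjective(0).getReaction())
    model.validate()
    return model


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def write_tsv(model: MetabolicModel, directory: Union[str, Path]) -> Dict[str, Path]:
    """Write three UTF-8 TSV tables: metabolites, reactions, genes.

    Stable columns:

    * ``<id>_metabolites.tsv``: id, name, compartment, formula, charge
    * ``<id>_reactions.tsv``: id, name, stoichiometry (``met:coef`` joined
      by ``;``), lower_bound, upper_bound, gene_rule, subsystem,
      ec_numbers, is_exchange
    * ``<id>_genes.tsv``: gene, reactions
    """
    model.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    met_df = pd.DataFrame(
        [{"id": m.id, "name": m.name, "compartment": m.compartment,
          "formula": format_formula(m.formula), "charge": m.charge}
         for m in model.metabolites.values()])
    rxn_df = pd.DataFrame(
        [{"id": r.id, "name": r.name,
          "stoichiometry": ";".join(
              f"{met}:{coef:g}" for met, coef in sorted(r.stoichiometry.items())),
          "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
          "gene_rule": r.gene_rule, "subsystem": r.subsystem,
          "ec_numbers": ",".join(r.ec_numbers),
          "is_exchange": r.is_exchange}
         for r in model.reactions.values()])
    gene_rxns: Dict[str, List[str]] = {g: [] for g in sorted(model.gene_ids)}
    for rxn in model.reactions.values():
        for gene in rxn.genes:
            gene_rxns[gene].append(rxn.id)
    gene_df = pd.DataFrame(
        [{"gene": g, "reactions": ";".join(sorted(rs))}
         for g, rs in gene_rxns.items()],
        columns=["gene", "reactions"])

    paths = {}
    for tag, df in (("metabolites", met_df), ("reactions", rxn_df),
                    ("genes", gene_df)):
        out = directory / f"{model.id}_{tag}.tsv"
        df.to_csv(out, sep="\t", index=False)
        paths[tag] = out
    return paths
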