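"""SBML read/write for :class:`~panfba.model.MetabolicModel`.

Models are written as SBML Level 2 Version 4 using the widespread COBRA
dialect of that era: flux bounds as ``LOWER_BOUND``/``UPPER_BOUND`` kinetic
law parameters and GPR rules as ``GENE_ASSOCIATION:`` lines in reaction
notes.  The parser accepts Level 2 dialects generally, tolerates missing
GPR notes (reactions then parse as non-gene-associated) and recognises

* exchange reactions: a single model species, or a species paired with a
  ``boundaryCondition`` partner;
* the demand/biomass reaction: id containing ``BIO`` (it becomes the
  objective).

Identifiers are sanitized to valid SBML SIds through a reversible escape
map (``__xHH__`` hex escapes), so ids such as ``EX_ac(e)`` survive a
round-trip losslessly.
"""

from __future__ import annotations

import re

import libsbml

from .gpr import GPR
from .model import Gene, Metabolite, MetabolicModel, Reaction

_SID_OK = re.compile(r"[A-Za-z0-9_]")
_ESCAPE = re.compile(r"__x([0-9a-fA-F]{2})__")


class SBMLParseError(ValueError):
    """Raised for malformed SBML input (with line info when available)."""


def sanitize_sid(raw: str) -> str:
    out = []
    for ch in raw:
        if _SID_OK.match(ch):
            out.append(ch)
        else:
            out.append(f"__x{ord(ch):02x}__")
    sid = "".join(out)
    if not sid or sid[0].isdigit():
        sid = "_" + sid
    return sid


def unsanitize_sid(sid: str) -> str:
    if sid.startswith("_") and sid[1:2].isdigit():
        sid = sid[1:]
    return _ESCAPE.sub(lambda m: chr(int(m.group(1), 16)), sid)


def _notes_string(entries: dict[str, str]) -> str:
    lines = "".join(f"<p>{k}: {v}</p>" for k, v in entries.items() if v)
    return (
        '<body xmlns="http://www.w3.org/1999/xhtml">' + lines + "</body>"
    )


def _parse_notes(node) -> dict[str, str]:
    out: dict[str, str] = {}
    if node is None or not node.isSetNotes():
        return out
    text = node.getNotesString()
    for match in re.finditer(r"<p>\s*([^:<]+?)\s*:\s*(.*?)\s*</p>", text, re.S):
        out[match.group(1).strip().upper()] = match.group(2).strip()
    return out


def write_sbml(model: MetabolicModel) -> str:
    """Serialize a model to an SBML Level 2 Version 4 string."""
    doc = libsbml.SBMLDocument(2, 4)
    sbml_model = doc.createModel()
    sbml_model.setId(sanitize_sid(model.model_id))
    sbml_model.setName(model.name)

    for comp_id in ("c", "e"):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setSize(1.0)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId("M_" + sanitize_sid(met.met_id))
        sp.setName(met.name or met.met_id)
        sp.setCompartment(met.compartment)
        sp.setInitialAmount(0.0)
        notes = {}
        if met.formula is not None:
            notes["FORMULA"] = met.formula
        if met.charge is not None:
            notes["CHARGE"] = str(met.charge)
        if notes:
            sp.setNotes(_notes_string(notes))

    for rxn in model.reactions.values():
        rx = sbml_model.createReaction()
        rx.setId("R_" + sanitize_sid(rxn.rxn_id))
        rx.setName(rxn.name or rxn.rxn_id)
        rx.setReversible(rxn.lb < 0)
        for met_id, coeff in rxn.stoich.items():
            if coeff < 0:
                ref = rx.createReactant()
            else:
                ref = rx.createProduct()
            ref.setSpecies("M_" + sanitize_sid(met_id))
            ref.setStoichiometry(abs(coeff))
        law = rx.createKineticLaw()
        law.setFormula("FLUX_VALUE")
        for pname, value in (("LOWER_BOUND", rxn.lb), ("UPPER_BOUND", rxn.ub)):
            par = law.createParameter()
            par.setId(pname)
            par.setValue(value)
            par.setUnits("mmol_per_gDW_per_hr")
        notes = {"KIND": rxn.kind}
        if not rxn.gpr.empty:
            notes["GENE_ASSOCIATION"] = rxn.gpr.to_string()
        if rxn.subsystem:
            notes["SUBSYSTEM"] = rxn.subsystem
        if model.objective_rxn_id == rxn.rxn_id:
            notes["OBJECTIVE"] = "1"
        rx.setNotes(_notes_string(notes))

    return libsbml.writeSBMLToString(doc)


def parse_sbml(source: str) -> MetabolicModel:
    """Parse SBML text (or a path to an SBML file) into a model."""
    if "<" in source:
        doc = libsbml.readSBMLFromString(source)
    else:
        doc = libsbml.readSBMLFromFile(source)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLParseError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLParseError("document contains no model")

    model = MetabolicModel(
        model_id=unsanitize_sid(sbml_model.getId() or "model"),
        name=sbml_model.getName() or "",
    )

    boundary: set[str] = set()
    for sp in sbml_model.getListOfSpecies():
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        notes = _parse_notes(sp)
        sid = sp.getId()
        met_id = unsanitize_sid(sid[2:] if sid.startswith("M_") else sid)
        compartment = sp.getCompartment() or "c"
        if compartment not in ("c", "e"):
            # outside/extra-organism compartments collapse onto 'e'
            compartment = "e"
        charge = None
        if "CHARGE" in notes:
            try:
                charge = int(float(notes["CHARGE"]))
            except ValueError:
                charge = None
        elif sp.isSetCharge():
            charge = sp.getCharge()
        model.add_metabolite(
            Metabolite(
                met_id=met_id,
                name=sp.getName() or met_id,
                formula=notes.get("FORMULA"),
                charge=charge,
                compartment=compartment,
            )
        )

    objective_id = None
    for rx in sbml_model.getListOfReactions():
        rid = rx.getId()
        rxn_id = unsanitize_sid(rid[2:] if rid.startswith("R_") else rid)
        stoich: dict[str, float] = {}
        for ref in rx.getListOfReactants():
            if ref.getSpecies() in boundary:
                continue
            sid = ref.getSpecies()
            met_id = unsanitize_sid(sid[2:] if sid.startswith("M_") else sid)
            if met_id not in model.metabolites:
                raise SBMLParseError(
                    f"reaction {rxn_id!r} references unknown species {sid!r}"
                )
            stoich[met_id] = stoich.get(met_id, 0.0) - ref.getStoichiometry()
        for ref in rx.getListOfProducts():
            if ref.getSpecies() in boundary:
                continue
            sid = ref.getSpecies()
            met_id = unsanitize_sid(sid[2:] if sid.startswith("M_") else sid)
            if met_id not in model.metabolites:
                raise SBMLParseError(
                    f"reaction {rxn_id!r} references unknown species {sid!r}"
                )
            stoich[met_id] = stoich.get(met_id, 0.0) + ref.getStoichiometry()
        if not stoich:
            continue  # pure boundary-to-boundary artifact

        lb, ub = None, None
        law = rx.getKineticLaw()
        if law is not None:
            for i in range(law.getNumParameters()):
                par = law.getParameter(i)
                if par.getId().upper() == "LOWER_BOUND":
                    lb = par.getValue()
                elif par.getId().upper() == "UPPER_BOUND":
                    ub = par.getValue()
        reversible = rx.getReversible()
        if lb is None:
            lb = -1000.0 if reversible else 0.0
        if ub is None:
            ub = 1000.0

        notes = _parse_notes(rx)
        gpr = GPR.from_string(notes.get("GENE_ASSOCIATION", ""))
        kind = notes.get("KIND", "").lower()
        if kind not in ("intra-system", "exchange", "demand"):
            # infer: demand = biomass reaction (id containing BIO);
            # exchange = single-species boundary form
            if "BIO" in rxn_id.upper():
                kind = "demand"
            elif len(stoich) == 1:
                kind = "exchange"
            else:
                kind = "intra-system"
        rxn = Reaction(
            rxn_id=rxn_id, stoich=stoich, lb=lb, ub=ub, gpr=gpr,
            name=rx.getName() or rxn_id,
            subsystem=notes.get("SUBSYSTEM", ""), kind=kind,
        )
        model.add_reaction(rxn)
        if notes.get("OBJECTIVE") == "1" or (objective_id is None and kind == "demand"):
            objective_id = rxn_id

    model.objective_rxn_id = objective_id
    for gene_id in sorted({g for r in model.reactions.values() for g in r.gpr.genes()}):
        model.add_gene(Gene(gene_id))
    return model
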