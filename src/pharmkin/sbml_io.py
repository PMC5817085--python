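"""SBML Level 3 Version 1 export/import of kinetic models.

Kinetic laws are emitted as explicit rate expressions (MathML via libsbml)
with local parameters; the law type travels as an SBO term on the kinetic
law (28 = Michaelis-Menten, 12 = mass action) and modifier roles as SBO
terms on the modifier references (13 = catalyst, 20 = inhibitor, local
parameter ``Ki_<species>`` holding the inhibition constant).  Readout names
are carried in the model notes.  ``import_sbml(export_sbml(m))`` rebuilds a
structurally identical model.
"""

from __future__ import annotations

import re

import libsbml

from .kinetics import KineticLaw, KineticModel, ModelError, Reaction, Species

SBO_MICHAELIS_MENTEN = 28
SBO_MASS_ACTION = 12
SBO_CATALYST = 13
SBO_INHIBITOR = 20

_LAW_BY_SBO = {SBO_MICHAELIS_MENTEN: "michaelis_menten", SBO_MASS_ACTION: "mass_action"}


def _check(status, what: str) -> None:
    if status not in (None, libsbml.LIBSBML_OPERATION_SUCCESS):
        raise ModelError(f"libsbml error while {what}: status {status}")


def _rate_formula(rxn: Reaction) -> str:
    law = rxn.law
    if law.law_type == "michaelis_menten":
        s = rxn.reactants[0][0]
        terms = [f"Vm * {s} / (Km + {s})"]
    else:
        terms = ["k"]
        for name, st in rxn.reactants:
            terms.append(name if st == 1 else f"{name}^{st}")
    terms.extend(law.modifiers)
    for name in law.inhibitors:
        terms.append(f"(1 / (1 + {name} / Ki_{name}))")
    return " * ".join(terms)


def export_sbml(model: KineticModel) -> str:
    """Serialise a model to an SBML L3V1 document string."""
    ns = libsbml.SBMLNamespaces(3, 1)
    doc = libsbml.SBMLDocument(ns)
    m = doc.createModel()
    _check(m.setId("signaling_network"), "setting model id")
    if model.readouts:
        notes = ('<notes><body xmlns="http://www.w3.org/1999/xhtml">'
                 f"<p>readouts: {', '.join(model.readouts)}</p></body></notes>")
        _check(m.setNotes(notes), "setting model notes")

    for comp_name in sorted({s.compartment for s in model.species}):
        c = m.createCompartment()
        _check(c.setId(comp_name), f"creating compartment {comp_name}")
        c.setSize(1.0)
        c.setConstant(True)
        c.setSpatialDimensions(3)

    for sp in model.species:
        if not libsbml.SyntaxChecker.isValidSBMLSId(sp.name):
            raise ModelError(f"species name {sp.name!r} is not a valid SBML identifier")
        s = m.createSpecies()
        _check(s.setId(sp.name), f"creating species {sp.name}")
        s.setCompartment(sp.compartment)
        s.setInitialConcentration(sp.init_um)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)

    for rxn in model.reactions:
        r = m.createReaction()
        _check(r.setId(rxn.id), f"creating reaction {rxn.id}")
        r.setReversible(False)
        r.setFast(False)
        for name, st in rxn.reactants:
            ref = r.createReactant()
            ref.setSpecies(name)
            ref.setStoichiometry(float(st))
            ref.setConstant(True)
        for name, st in rxn.products:
            ref = r.createProduct()
            ref.setSpecies(name)
            ref.setStoichiometry(float(st))
            ref.setConstant(True)
        for name in rxn.law.modifiers:
            ref = r.createModifier()
            ref.setSpecies(name)
            ref.setSBOTerm(SBO_CATALYST)
        for name in rxn.law.inhibitors:
            ref = r.createModifier()
            ref.setSpecies(name)
            ref.setSBOTerm(SBO_INHIBITOR)

        kl = r.createKineticLaw()
        kl.setSBOTerm(SBO_MICHAELIS_MENTEN if rxn.law.law_type == "michaelis_menten"
                      else SBO_MASS_ACTION)
        for pname, val in rxn.law.params.items():
            p = kl.createLocalParameter()
            p.setId(pname)
            p.setValue(float(val))
        for name, ki in rxn.law.inhibitors.items():
            p = kl.createLocalParameter()
            p.setId(f"Ki_{name}")
            p.setValue(float(ki))
        math = libsbml.parseL3Formula(_rate_formula(rxn))
        if math is None:
            raise ModelError(f"could not build rate expression for reaction {rxn.id}")
        _check(kl.setMath(math), f"setting kinetic law of {rxn.id}")

    return libsbml.writeSBMLToString(doc)


def import_sbml(source: str) -> KineticModel:
    """Rebuild a :class:`KineticModel` from an SBML string (or file path)."""
    if "<sbml" in source:
        doc = libsbml.readSBMLFromString(source)
    else:
        doc = libsbml.readSBMLFromFile(str(source))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelError("SBML document has errors: "
                         + doc.getErrorLog().toString())
    m = doc.getModel()
    if m is None:
        raise ModelError("SBML document contains no model")

    species = []
    for i in range(m.getNumSpecies()):
        s = m.getSpecies(i)
        init = s.getInitialConcentration()
        if not (init == init):  # NaN -> unset
            init = 0.0
        species.append(Species(s.getId(), float(init), s.getCompartment() or "cell"))

    reactions = []
    for i in range(m.getNumReactions()):
        r = m.getReaction(i)
        kl = r.getKineticLaw()
        if kl is None or kl.getSBOTerm() not in _LAW_BY_SBO:
            raise ModelError(f"reaction {r.getId()!r} has an unsupported or missing rate-law type")
        law_type = _LAW_BY_SBO[kl.getSBOTerm()]
        params = {}
        for j in range(kl.getNumLocalParameters()):
            p = kl.getLocalParameter(j)
            params[p.getId()] = float(p.getValue())
        modifiers, inhibitors = [], {}
        for j in range(r.getNumModifiers()):
            ref = r.getModifier(j)
            if ref.getSBOTerm() == SBO_INHIBITOR:
                key = f"Ki_{ref.getSpecies()}"
                if key not in params:
                    raise ModelError(f"reaction {r.getId()!r}: inhibitor {ref.getSpecies()!r} "
                                     f"lacks local parameter {key}")
                inhibitors[ref.getSpecies()] = params.pop(key)
            else:
                modifiers.append(ref.getSpecies())
        law = KineticLaw(law_type=law_type, params=params, modifiers=modifiers,
                         inhibitors=inhibitors)
        reactions.append(Reaction(
            id=r.getId(),
            reactants=[(r.getReactant(j).getSpecies(), int(r.getReactant(j).getStoichiometry()))
                       for j in range(r.getNumReactants())],
            products=[(r.getProduct(j).getSpecies(), int(r.getProduct(j).getStoichiometry()))
                      for j in range(r.getNumProducts())],
            law=law))

    readouts: list[str] = []
    notes = m.getNotesString() if m.isSetNotes() else ""
    match = re.search(r"readouts:\s*([^<]+)", notes)
    if match:
        readouts = [x.strip() for x in match.group(1).split(",") if x.strip()]
    return KineticModel(species, reactions, readouts=readouts)


def validate_sbml(source: str) -> int:
    """Structural consistency check; returns the number of errors."""
    doc = (libsbml.readSBMLFromString(source) if "<sbml" in source
           else libsbml.readSBMLFromFile(str(source)))
    doc.checkConsistency()
    return doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR)
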