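"""SBML core-subset reader (Level 2/3): species, reactions, compartments.

Species become entities annotated with their compartment; reactions become
hyperedges with modifiers as catalysts and the reversible flag honored.
Constructs outside the subset (rules, events, function definitions) are
skipped with a logged count.
"""

from __future__ import annotations

import logging

from lxml import etree

from ..errors import FormatError
from ..model import Entity, Kind, NetworkModel, ReactionHyperedge

logger = logging.getLogger(__name__)

_UNSUPPORTED = {
    "listOfRules", "listOfEvents", "listOfFunctionDefinitions",
    "listOfConstraints", "listOfInitialAssignments",
}


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find(parent, name):
    for child in parent:
        if _local(child.tag) == name:
            return child
    return None


def _findall(parent, name):
    return [c for c in parent if _local(c.tag) == name]


def read_sbml_subset(xml: str | bytes) -> NetworkModel:
    if isinstance(xml, str):
        xml = xml.encode()
    try:
        root = etree.fromstring(xml)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed SBML: {exc}") from exc
    if _local(root.tag) != "sbml":
        raise FormatError(f"not an SBML document (root <{_local(root.tag)}>)")
    sbml_model = _find(root, "model")
    if sbml_model is None:
        raise FormatError("SBML document has no <model>")

    model = NetworkModel(name=sbml_model.get("id", "sbml"))

    compartments = {}
    loc = _find(sbml_model, "listOfCompartments")
    if loc is not None:
        for comp in _findall(loc, "compartment"):
            compartments[comp.get("id")] = comp.get("name") or comp.get("id")

    los = _find(sbml_model, "listOfSpecies")
    if los is not None:
        for sp in _findall(los, "species"):
            sid = sp.get("id")
            comp = sp.get("compartment")
            model.add_entity(Entity(
                sid,
                kind=Kind.COMPOUND,
                label=sp.get("name") or sid,
                compartments=[compartments.get(comp, comp)] if comp else [],
            ))

    n_skipped = 0
    for child in sbml_model:
        if _local(child.tag) in _UNSUPPORTED:
            n_skipped += len(list(child))
    if n_skipped:
        logger.info("SBML: skipped %d unsupported constructs", n_skipped)

    lor = _find(sbml_model, "listOfReactions")
    if lor is not None:
        for rxn in _findall(lor, "reaction"):
            rid = rxn.get("id")

            def refs(list_name, rxn=rxn):
                lst = _find(rxn, list_name)
                if lst is None:
                    return []
                return [
                    (r.get("species"), float(r.get("stoichiometry", 1)))
                    for r in lst
                    if _local(r.tag) in ("speciesReference", "modifierSpeciesReference")
                ]

            subs = refs("listOfReactants")
            prods = refs("listOfProducts")
            mods = [s for s, _ in refs("listOfModifiers")]
            if not subs or not prods:
                logger.warning("SBML reaction %s lacks reactants or products, skipped", rid)
                continue
            reversible = rxn.get("reversible", "true").lower() == "true"
            model.add_reaction(ReactionHyperedge(
                id=rid, substrates=subs, products=prods, catalysts=mods,
                reversible=reversible, label=rxn.get("name") or rid,
            ))

    model.clear_dirty()
    return model
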