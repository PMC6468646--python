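"""Minimal SBML Level 3 export and round-trip import.

The writer emits one SBML species per model species (with initial
concentrations in nM), one compartment per cellular compartment, and one
reaction per model reaction with its kinetic law spelled out in MathML and
its parameters (k and c, or Vmax and Km) as local parameters.  The rate-law
kind, module tag and input flag are carried in an annotation namespace so
that `read_sbml` can reconstruct the exact network; round-tripping is
guaranteed for documents this package wrote, not for arbitrary third-party
SBML.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

from .errors import ModelSchemaError
from .network import RateLaw, Reaction, ReactionNetwork, Species

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://aktnfkb.invalid/sbml-annotations"

__all__ = ["write_sbml", "read_sbml"]


def _math(expr) -> ET.Element:
    """Build a MathML <math> element from a nested prefix expression."""
    math = ET.Element(f"{{{MATHML_NS}}}math")
    math.append(_math_node(expr))
    return math


def _math_node(expr) -> ET.Element:
    if isinstance(expr, (int, float)):
        cn = ET.Element(f"{{{MATHML_NS}}}cn")
        cn.text = repr(float(expr))
        return cn
    if isinstance(expr, str):
        ci = ET.Element(f"{{{MATHML_NS}}}ci")
        ci.text = f" {expr} "
        return ci
    op, *args = expr
    apply = ET.Element(f"{{{MATHML_NS}}}apply")
    apply.append(ET.Element(f"{{{MATHML_NS}}}{op}"))
    for a in args:
        apply.append(_math_node(a))
    return apply


def _kinetic_expr(r: Reaction) -> tuple:
    law = r.rate_law
    if law.kind == "michaelis_menten":
        s = r.substrate
        return ("divide", ("times", "Vmax", s), ("plus", "Km", s))
    factors: list = ["k"]
    for sid, st in r.reactants:
        factors.extend([sid] * st)
    expr: tuple = ("times", *factors) if len(factors) > 1 else factors[0]
    return expr


def write_sbml(net: ReactionNetwork, path) -> None:
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    ET.register_namespace("akb", ANNOT_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": str(net.metadata.get("name", "model"))})

    loc = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for comp in sorted({s.compartment for s in net.species}):
        ET.SubElement(
            loc, f"{{{SBML_NS}}}compartment",
            {"id": comp, "constant": "true", "spatialDimensions": "3", "size": "1"},
        )

    los = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for s in net.species:
        el = ET.SubElement(
            los, f"{{{SBML_NS}}}species",
            {
                "id": s.id,
                "name": s.name,
                "compartment": s.compartment,
                "initialConcentration": repr(s.initial_nM),
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "true" if s.is_input else "false",
                "constant": "false",
            },
        )
        ann = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
        ET.SubElement(ann, f"{{{ANNOT_NS}}}speciesInfo", {"isInput": str(s.is_input).lower()})

    lor = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for r in net.reactions:
        el = ET.SubElement(lor, f"{{{SBML_NS}}}reaction", {"id": r.id, "reversible": "false"})
        ann = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
        ET.SubElement(
            ann, f"{{{ANNOT_NS}}}reactionInfo",
            {"kind": r.rate_law.kind, "module": r.module},
        )
        if r.reactants:
            lr = ET.SubElement(el, f"{{{SBML_NS}}}listOfReactants")
            for sid, st in r.reactants:
                ET.SubElement(
                    lr, f"{{{SBML_NS}}}speciesReference",
                    {"species": sid, "stoichiometry": str(st), "constant": "true"},
                )
        if r.products:
            lp = ET.SubElement(el, f"{{{SBML_NS}}}listOfProducts")
            for sid, st in r.products:
                ET.SubElement(
                    lp, f"{{{SBML_NS}}}speciesReference",
                    {"species": sid, "stoichiometry": str(st), "constant": "true"},
                )
        kl = ET.SubElement(el, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_math(_kinetic_expr(r)))
        lop = ET.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
        law = r.rate_law
        if law.kind == "mass_action":
            params = {"k": law.k, "c": law.c}
        else:
            params = {"Vmax": law.vmax, "Km": law.km}
        for pid, val in params.items():
            ET.SubElement(
                lop, f"{{{SBML_NS}}}localParameter", {"id": pid, "value": repr(float(val))}
            )

    ET.ElementTree(sbml).write(path, xml_declaration=True, encoding="unicode")


def _local_params(kl: ET.Element) -> dict[str, float]:
    out = {}
    for lp in kl.iter(f"{{{SBML_NS}}}localParameter"):
        out[lp.get("id")] = float(lp.get("value"))
    return out


def read_sbml(path) -> ReactionNetwork:
    """Reconstruct a ReactionNetwork from a document written by write_sbml."""
    tree = ET.parse(path)
    model = tree.getroot().find(f"{{{SBML_NS}}}model")
    if model is None:
        raise ModelSchemaError(f"{path}: no SBML model element")

    species = []
    for el in model.iter(f"{{{SBML_NS}}}species"):
        info = el.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}speciesInfo")
        species.append(
            Species(
                id=el.get("id"),
                name=el.get("name", el.get("id")),
                compartment=el.get("compartment"),
                initial_nM=float(el.get("initialConcentration", "0")),
                is_input=(info is not None and info.get("isInput") == "true"),
            )
        )

    reactions = []
    for el in model.iter(f"{{{SBML_NS}}}reaction"):
        info = el.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}reactionInfo")
        if info is None:
            raise ModelSchemaError(
                f"reaction {el.get('id')!r}: missing annotation; only documents "
                "written by this package can be round-tripped"
            )
        kl = el.find(f"{{{SBML_NS}}}kineticLaw")
        params = _local_params(kl) if kl is not None else {}
        kind = info.get("kind")
        if kind == "mass_action":
            law = RateLaw(kind=kind, k=params["k"], c=params.get("c", 0.0))
        else:
            law = RateLaw(kind=kind, vmax=params["Vmax"], km=params["Km"])

        def refs(tag):
            parent = el.find(f"{{{SBML_NS}}}{tag}")
            if parent is None:
                return ()
            return tuple(
                (sr.get("species"), int(float(sr.get("stoichiometry", "1"))))
                for sr in parent.iter(f"{{{SBML_NS}}}speciesReference")
            )

        reactions.append(
            Reaction(
                id=el.get("id"),
                reactants=refs("listOfReactants"),
                products=refs("listOfProducts"),
                rate_law=law,
                module=info.get("module"),
            )
        )
    name = model.get("id", "model")
    return ReactionNetwork(species=species, reactions=reactions, metadata={"name": name})
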