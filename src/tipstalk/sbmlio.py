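"""SBML Level 3 export/import for model exchange.

Export writes a plain SBML L3V1 document with stdlib XML tooling:
compartments, species (initial concentrations in µM, constant/boundary
flags), global parameters, and reactions whose kinetic laws are rendered as
content MathML in the canonical shapes of the three supported law families
(mass action, Michaelis-Menten, Hill, each with optional enzyme factor and
activator/inhibitor modifier factors).  A package annotation (own XML
namespace, as SBML annotations are designed for) carries the structured law
description plus parameter status/group/bounds and observable definitions,
so an export→import round trip is exact.

Import first honours the annotation when present; for foreign documents it
falls back to structural classification of the MathML into the three
families.  Anything outside them — e.g. an arbitrary rational rate law —
raises :class:`UnsupportedConstructError` naming the reaction, rather than
silently mis-reading the kinetics.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

from .network import (
    ModelDefinition,
    Modifier,
    Parameter,
    Reaction,
    Species,
)

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "urn:tipstalk:model-annotation"

ET.register_namespace("", SBML_NS)
ET.register_namespace("math", MATHML_NS)
ET.register_namespace("ts", ANNOT_NS)


class UnsupportedConstructError(ValueError):
    """An SBML construct outside the supported kinetic-law families."""


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


# ---------------------------------------------------------------------------
# MathML rendering
# ---------------------------------------------------------------------------

def _ci(parent, name):
    e = ET.SubElement(parent, _q(MATHML_NS, "ci"))
    e.text = f" {name} "
    return e


def _cn(parent, value):
    e = ET.SubElement(parent, _q(MATHML_NS, "cn"))
    e.text = f" {value:g} "
    return e


def _apply(parent, op):
    a = ET.SubElement(parent, _q(MATHML_NS, "apply"))
    ET.SubElement(a, _q(MATHML_NS, op))
    return a


def _power(parent, base_name, exp_name):
    a = _apply(parent, "power")
    _ci(a, base_name)
    if isinstance(exp_name, str):
        _ci(a, exp_name)
    else:
        _cn(a, exp_name)
    return a


def _law_mathml(r: Reaction) -> ET.Element:
    math = ET.Element(_q(MATHML_NS, "math"))
    top = _apply(math, "times")
    lp = r.law_params
    if r.law == "mass_action":
        _ci(top, lp["k"])
        for sp, st in r.reactants:
            if st == 1:
                _ci(top, sp)
            else:
                _power(top, sp, st)
    else:
        _ci(top, lp["vmax"])
        if "enzyme" in lp:
            _ci(top, lp["enzyme"])
        sub = lp["substrate"]
        div = _apply(top, "divide")
        if r.law == "michaelis_menten":
            _ci(div, sub)
            den = _apply(div, "plus")
            _ci(den, lp["km"])
            _ci(den, sub)
        else:
            _power(div, sub, lp["n"])
            den = _apply(div, "plus")
            _power(den, lp["k"], lp["n"])
            _power(den, sub, lp["n"])
        for sp, st in r.reactants:
            if sp != sub:
                if st == 1:
                    _ci(top, sp)
                else:
                    _power(top, sp, st)
    for m in r.modifiers:
        if m.role == "activator":
            term = _apply(top, "plus")  # (1 + (S/K)^n)
        else:
            div = _apply(top, "divide")  # 1 / (1 + (S/K)^n)
            _cn(div, 1)
            term = _apply(div, "plus")
        _cn(term, 1)
        plain = not isinstance(m.n, str) and m.n == 1.0
        host = term if plain else _apply(term, "power")
        ratio = _apply(host, "divide")
        _ci(ratio, m.species)
        _ci(ratio, m.k_param)
        if not plain:
            if isinstance(m.n, str):
                _ci(host, m.n)
            else:
                _cn(host, m.n)
    return math


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_sbml(model: ModelDefinition, path) -> None:
    """Write the model as an SBML Level 3 Version 1 document."""
    model.validate()
    root = ET.Element(_q(SBML_NS, "sbml"), {"level": "3", "version": "1"})
    mdl = ET.SubElement(root, _q(SBML_NS, "model"), {"id": model.name.replace("-", "_")})

    annot = ET.SubElement(mdl, _q(SBML_NS, "annotation"))
    pkg = ET.SubElement(annot, _q(ANNOT_NS, "tipstalk"))
    obs_el = ET.SubElement(pkg, _q(ANNOT_NS, "observables"))
    for name, expr in model.observables.items():
        ET.SubElement(obs_el, _q(ANNOT_NS, "observable"), {"name": name, "expr": expr})

    comps = ET.SubElement(mdl, _q(SBML_NS, "listOfCompartments"))
    for c in sorted({s.compartment for s in model.species}):
        ET.SubElement(comps, _q(SBML_NS, "compartment"),
                      {"id": c, "constant": "true", "spatialDimensions": "3", "size": "1"})

    sps = ET.SubElement(mdl, _q(SBML_NS, "listOfSpecies"))
    for s in model.species:
        attrs = {"id": s.name, "compartment": s.compartment,
                 "initialConcentration": repr(float(s.initial_value)),
                 "constant": "true" if s.is_constant else "false",
                 "boundaryCondition": "true" if s.is_constant else "false",
                 "hasOnlySubstanceUnits": "false"}
        el = ET.SubElement(sps, _q(SBML_NS, "species"), attrs)
        if s.is_state_flux or s.initial_from_param:
            a = ET.SubElement(el, _q(SBML_NS, "annotation"))
            extra = {}
            if s.is_state_flux:
                extra["stateFlux"] = "true"
            if s.initial_from_param:
                extra["initialFromParameter"] = s.initial_from_param
            ET.SubElement(a, _q(ANNOT_NS, "speciesInfo"), extra)

    pars = ET.SubElement(mdl, _q(SBML_NS, "listOfParameters"))
    for p in model.parameters.values():
        el = ET.SubElement(pars, _q(SBML_NS, "parameter"),
                           {"id": p.name, "value": repr(float(p.value)), "constant": "true"})
        a = ET.SubElement(el, _q(SBML_NS, "annotation"))
        extra = {"status": p.status, "group": p.group, "units": p.units}
        if p.bounds is not None:
            extra["lower"] = repr(float(p.bounds[0]))
            extra["upper"] = repr(float(p.bounds[1]))
        ET.SubElement(a, _q(ANNOT_NS, "parameterInfo"), extra)

    rxs = ET.SubElement(mdl, _q(SBML_NS, "listOfReactions"))
    for r in model.reactions:
        el = ET.SubElement(rxs, _q(SBML_NS, "reaction"),
                           {"id": r.name, "reversible": "false", "fast": "false"})
        a = ET.SubElement(el, _q(SBML_NS, "annotation"))
        law_el = ET.SubElement(a, _q(ANNOT_NS, "kineticLawSpec"),
                               {"law": r.law, "scope": r.scope, "module": r.module})
        for slot, ref in r.law_params.items():
            ET.SubElement(law_el, _q(ANNOT_NS, "lawParam"), {"slot": slot, "ref": ref})
        for m in r.modifiers:
            ET.SubElement(law_el, _q(ANNOT_NS, "regulator"),
                          {"species": m.species, "role": m.role, "k": m.k_param,
                           "n": m.n if isinstance(m.n, str) else repr(float(m.n))})
        if r.reactants:
            lst = ET.SubElement(el, _q(SBML_NS, "listOfReactants"))
            for sp, st in r.reactants:
                ET.SubElement(lst, _q(SBML_NS, "speciesReference"),
                              {"species": sp, "stoichiometry": str(st), "constant": "true"})
        if r.products:
            lst = ET.SubElement(el, _q(SBML_NS, "listOfProducts"))
            for sp, st in r.products:
                ET.SubElement(lst, _q(SBML_NS, "speciesReference"),
                              {"species": sp, "stoichiometry": str(st), "constant": "true"})
        mods = [m.species for m in r.modifiers]
        for slot in ("substrate", "enzyme"):
            ref = r.law_params.get(slot)
            if ref and ref not in [sp for sp, _ in r.reactants] and ref not in mods:
                mods.append(ref)
        if mods:
            lst = ET.SubElement(el, _q(SBML_NS, "listOfModifiers"))
            for sp in dict.fromkeys(mods):
                ET.SubElement(lst, _q(SBML_NS, "modifierSpeciesReference"), {"species": sp})
        kl = ET.SubElement(el, _q(SBML_NS, "kineticLaw"))
        kl.append(_law_mathml(r))

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

def _parse_mathml(el):
    """MathML element → nested tuples ('op', args...) | ('ci', name) | ('cn', value)."""
    tag = el.tag.split("}")[-1]
    if tag == "math":
        kids = list(el)
        if len(kids) != 1:
            raise UnsupportedConstructError("math element must have one child")
        return _parse_mathml(kids[0])
    if tag == "ci":
        return ("ci", el.text.strip())
    if tag == "cn":
        return ("cn", float(el.text.strip()))
    if tag == "apply":
        kids = list(el)
        op = kids[0].tag.split("}")[-1]
        return (op, *[_parse_mathml(k) for k in kids[1:]])
    raise UnsupportedConstructError(f"unsupported MathML element <{tag}>")


def _flatten_times(node):
    if node[0] != "times":
        return [node]
    out = []
    for a in node[1:]:
        out.extend(_flatten_times(a))
    return out


def _classify_law(node, rid: str, param_ids: set, species_ids: set,
                  reactants: list) -> tuple[str, dict]:
    """Structural classification of canonical MathML into the law families."""
    factors = _flatten_times(node)
    k_params: list[str] = []
    mm: dict | None = None
    species_factors: list[str] = []
    for f in factors:
        if f[0] == "ci" and f[1] in param_ids:
            k_params.append(f[1])
        elif f[0] == "ci" and f[1] in species_ids:
            species_factors.append(f[1])
        elif f[0] == "power" and f[1][0] == "ci" and f[1][1] in species_ids \
                and f[2][0] == "cn" and float(f[2][1]).is_integer():
            species_factors.extend([f[1][1]] * int(f[2][1]))
        elif f[0] == "divide" and mm is None:
            mm = _classify_ratio(f, rid, param_ids, species_ids)
        else:
            raise UnsupportedConstructError(
                f"reaction {rid!r}: rate law outside the mass-action/"
                f"Michaelis-Menten/Hill families")
    if len(k_params) != 1:
        raise UnsupportedConstructError(
            f"reaction {rid!r}: expected exactly one rate parameter, found {k_params}")
    k = k_params[0]
    if mm is None:
        return ("mass_action", {"k": k})
    law, lp = mm
    lp["vmax"] = k
    extra = [s for s in species_factors if s != lp["substrate"]
             and s not in [sp for sp, _ in reactants]]
    if len(extra) == 1:
        lp["enzyme"] = extra[0]
    elif len(extra) > 1:
        raise UnsupportedConstructError(
            f"reaction {rid!r}: multiple non-reactant concentration factors")
    return (law, lp)


def _classify_ratio(node, rid, param_ids, species_ids):
    _, num, den = node
    if num[0] == "ci" and num[1] in species_ids and den[0] == "plus" and len(den) == 3:
        a, b = den[1], den[2]
        if a[0] == "ci" and a[1] in param_ids and b == num:
            return ("michaelis_menten", {"km": a[1], "substrate": num[1]})
        if b[0] == "ci" and b[1] in param_ids and a == num:
            return ("michaelis_menten", {"km": b[1], "substrate": num[1]})
    if num[0] == "power" and num[1][0] == "ci" and num[1][1] in species_ids \
            and den[0] == "plus" and len(den) == 3:
        sub = num[1][1]
        nexp = num[2]
        kterm, sterm = den[1], den[2]
        if sterm != num:
            kterm, sterm = sterm, kterm
        if sterm == num and kterm[0] == "power" and kterm[1][0] == "ci" \
                and kterm[1][1] in param_ids and kterm[2] == nexp \
                and nexp[0] == "ci" and nexp[1] in param_ids:
            return ("hill", {"k": kterm[1][1], "n": nexp[1], "substrate": sub})
    raise UnsupportedConstructError(
        f"reaction {rid!r}: rational rate law outside the supported families")


def import_sbml(path) -> ModelDefinition:
    """Read an SBML Level 3 document into a :class:`ModelDefinition`."""
    tree = ET.parse(path)
    root = tree.getroot()
    mdl = root.find(_q(SBML_NS, "model"))
    if mdl is None:
        raise UnsupportedConstructError("document has no <model> element")
    out = ModelDefinition(name=mdl.get("id", "model").replace("_", "-"))

    for el in mdl.iter(_q(SBML_NS, "species")):
        info = el.find(f"{_q(SBML_NS, 'annotation')}/{_q(ANNOT_NS, 'speciesInfo')}")
        out.species.append(Species(
            name=el.get("id"),
            compartment=el.get("compartment", "cell1"),
            initial_value=float(el.get("initialConcentration", "0")),
            is_constant=el.get("constant") == "true",
            is_state_flux=info is not None and info.get("stateFlux") == "true",
            initial_from_param=info.get("initialFromParameter") if info is not None else None,
        ))

    plist = mdl.find(_q(SBML_NS, "listOfParameters"))
    if plist is not None:
        for el in plist.findall(_q(SBML_NS, "parameter")):
            info = el.find(f"{_q(SBML_NS, 'annotation')}/{_q(ANNOT_NS, 'parameterInfo')}")
            bounds = None
            status, group, units = "assumed", "none", ""
            if info is not None:
                status = info.get("status", "assumed")
                group = info.get("group", "none")
                units = info.get("units", "")
                if info.get("lower") is not None:
                    bounds = (float(info.get("lower")), float(info.get("upper")))
            out.parameters[el.get("id")] = Parameter(
                el.get("id"), float(el.get("value", "0")),
                units=units, status=status, group=group, bounds=bounds)

    param_ids = set(out.parameters)
    species_ids = {s.name for s in out.species}
    comp_of = {s.name: s.compartment for s in out.species}

    for el in mdl.iter(_q(SBML_NS, "reaction")):
        rid = el.get("id")
        reactants, products = [], []
        lst = el.find(_q(SBML_NS, "listOfReactants"))
        if lst is not None:
            reactants = [(sr.get("species"), int(float(sr.get("stoichiometry", "1"))))
                         for sr in lst.findall(_q(SBML_NS, "speciesReference"))]
        lst = el.find(_q(SBML_NS, "listOfProducts"))
        if lst is not None:
            products = [(sr.get("species"), int(float(sr.get("stoichiometry", "1"))))
                        for sr in lst.findall(_q(SBML_NS, "speciesReference"))]
        spec = el.find(f"{_q(SBML_NS, 'annotation')}/{_q(ANNOT_NS, 'kineticLawSpec')}")
        if spec is not None:
            law = spec.get("law")
            lp = {lpe.get("slot"): lpe.get("ref")
                  for lpe in spec.findall(_q(ANNOT_NS, "lawParam"))}
            mods = []
            for me in spec.findall(_q(ANNOT_NS, "regulator")):
                n_raw = me.get("n")
                n = n_raw if n_raw in param_ids else float(n_raw)
                mods.append(Modifier(me.get("species"), me.get("role"), me.get("k"), n))
            scope, module = spec.get("scope", "intra-cell1"), spec.get("module", "")
        else:
            kl = el.find(_q(SBML_NS, "kineticLaw"))
            if kl is None:
                raise UnsupportedConstructError(f"reaction {rid!r}: no kinetic law")
            math = kl.find(_q(MATHML_NS, "math"))
            node = _parse_mathml(math)
            law, lp = _classify_law(node, rid, param_ids, species_ids, reactants)
            mods = []
            cells = {comp_of[sp] for sp, _ in reactants + products} & {"cell1", "cell2"}
            scope = "trans" if len(cells) == 2 else (
                f"intra-{next(iter(cells))}" if cells else "intra-cell1")
            module = ""
        out.reactions.append(Reaction(rid, reactants, products, law=law,
                                      law_params=lp, modifiers=mods,
                                      scope=scope, module=module))

    obs = mdl.find(f"{_q(SBML_NS, 'annotation')}/{_q(ANNOT_NS, 'tipstalk')}"
                   f"/{_q(ANNOT_NS, 'observables')}")
    if obs is not None:
        for o in obs.findall(_q(ANNOT_NS, "observable")):
            out.observables[o.get("name")] = o.get("expr")

    out.validate()
    return out
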