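"""Structured text (YAML) serialization for models and protocols.

The schema mirrors the in-memory types one-to-one:

model:
  name: str
  species:    [{name, compartment, initial_value, is_constant, is_state_flux,
                initial_from_param}]
  parameters: [{name, value, units, status, group, bounds: [lo, hi] | null}]
  reactions:  [{name, reactants: [[species, stoich], ...], products: [...],
                law, law_params: {slot: ref}, modifiers: [{species, role, k, n}],
                scope, module}]
  observables: {name: expression}

protocol:
  {vegf_cell1, vegf_cell2, o2, dapt, duration, pre_equilibrate_h,
   events: [[time_h, species, value], ...]}

A two-cell build request can instead be given as
``{build: two-cell, modules: [...], parameter_overrides: {...},
initial_overrides: {...}}`` and is materialised via
:func:`tipstalk.ecmodel.build_two_cell_model`.
"""

from __future__ import annotations

import yaml

from .ecmodel import ECModelConfig, build_two_cell_model
from .network import ModelDefinition, Modifier, Parameter, Reaction, Species
from .protocols import StimulusProtocol


def model_to_dict(model: ModelDefinition) -> dict:
    return {
        "name": model.name,
        "species": [
            {"name": s.name, "compartment": s.compartment,
             "initial_value": float(s.initial_value),
             "is_constant": s.is_constant, "is_state_flux": s.is_state_flux,
             "initial_from_param": s.initial_from_param}
            for s in model.species],
        "parameters": [
            {"name": p.name, "value": float(p.value), "units": p.units,
             "status": p.status, "group": p.group,
             "bounds": list(p.bounds) if p.bounds else None}
            for p in model.parameters.values()],
        "reactions": [
            {"name": r.name,
             "reactants": [[sp, int(st)] for sp, st in r.reactants],
             "products": [[sp, int(st)] for sp, st in r.products],
             "law": r.law, "law_params": dict(r.law_params),
             "modifiers": [{"species": m.species, "role": m.role,
                            "k": m.k_param, "n": m.n} for m in r.modifiers],
             "scope": r.scope, "module": r.module}
            for r in model.reactions],
        "observables": dict(model.observables),
    }


def model_from_dict(d: dict) -> ModelDefinition:
    if d.get("build") == "two-cell":
        cfg = ECModelConfig(
            modules=tuple(d.get("modules", ECModelConfig().modules)),
            parameter_overrides=d.get("parameter_overrides", {}) or {},
            initial_overrides=d.get("initial_overrides", {}) or {})
        return build_two_cell_model(cfg)
    m = ModelDefinition(name=d.get("name", "model"))
    for s in d.get("species", []):
        m.species.append(Species(
            name=s["name"], compartment=s.get("compartment", "cell1"),
            initial_value=float(s.get("initial_value", 0.0)),
            is_constant=bool(s.get("is_constant", False)),
            is_state_flux=bool(s.get("is_state_flux", False)),
            initial_from_param=s.get("initial_from_param")))
    for p in d.get("parameters", []):
        b = p.get("bounds")
        m.parameters[p["name"]] = Parameter(
            p["name"], float(p["value"]), units=p.get("units", ""),
            status=p.get("status", "assumed"), group=p.get("group", "none"),
            bounds=tuple(b) if b else None)
    for r in d.get("reactions", []):
        m.reactions.append(Reaction(
            name=r["name"],
            reactants=[(sp, int(st)) for sp, st in r.get("reactants", [])],
            products=[(sp, int(st)) for sp, st in r.get("products", [])],
            law=r.get("law", "mass_action"), law_params=dict(r.get("law_params", {})),
            modifiers=[Modifier(x["species"], x["role"], x["k"], x.get("n", 1.0))
                       for x in r.get("modifiers", [])],
            scope=r.get("scope", "intra-cell1"), module=r.get("module", "")))
    m.observables = dict(d.get("observables", {}))
    m.validate()
    return m


def protocol_to_dict(p: StimulusProtocol) -> dict:
    return {"vegf_cell1": p.vegf_cell1, "vegf_cell2": p.vegf_cell2,
            "o2": p.o2, "dapt": p.dapt, "duration": p.duration,
            "pre_equilibrate_h": p.pre_equilibrate_h,
            "events": [[t, sp, v] for t, sp, v in p.events]}


def protocol_from_dict(d: dict) -> StimulusProtocol:
    return StimulusProtocol(
        vegf_cell1=float(d.get("vegf_cell1", 0.0)),
        vegf_cell2=float(d.get("vegf_cell2", 0.0)),
        o2=float(d.get("o2", 209.0)), dapt=float(d.get("dapt", 0.0)),
        duration=float(d.get("duration", 12.0)),
        pre_equilibrate_h=float(d.get("pre_equilibrate_h", 24.0)),
        events=[(float(t), sp, float(v)) for t, sp, v in d.get("events", [])])


def save_model(model: ModelDefinition, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> ModelDefinition:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


def save_protocol(protocol: StimulusProtocol, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(protocol_to_dict(protocol), fh, sort_keys=False)


def load_protocol(path) -> StimulusProtocol:
    with open(path) as fh:
        return protocol_from_dict(yaml.safe_load(fh))
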