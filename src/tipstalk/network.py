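"""Generic reaction-network representation and ODE right-hand-side assembly.

A :class:`ModelDefinition` is a list of species, a list of reactions drawn
from three kinetic-law families (mass action, Michaelis-Menten, Hill), a
named parameter registry, and named algebraic observables.  The network is
compiled once into a fast flux function; the ODE right-hand side is the
stoichiometry matrix applied to the flux vector, so the self-consistency
``dy/dt == S @ flux`` holds by construction.

Unit convention: concentrations in µM, time internally in seconds
(user-facing time grids are in hours and converted at the simulation layer).
Negative state values, which stiff solvers can transiently produce, are
clamped to zero inside flux evaluation and counted on the compiled RHS.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

MASS_ACTION = "mass_action"
MICHAELIS_MENTEN = "michaelis_menten"
HILL = "hill"
LAW_FAMILIES = (MASS_ACTION, MICHAELIS_MENTEN, HILL)

COMPARTMENTS = ("cell1", "cell2", "extracellular")


class ModelValidationError(ValueError):
    """The model violates a structural invariant."""


class UnresolvedParameterError(ModelValidationError):
    """A kinetic law references a parameter absent from the registry."""


@dataclass
class Species:
    """A chemical species (state variable) in one compartment.

    ``is_constant`` species keep a zero derivative (e.g. HIF1β, O₂, the
    extracellular VEGF reservoir).  ``is_state_flux`` marks pseudo-species
    whose value is interpreted as a flux (the CRAC current Jcrac).
    ``initial_from_param`` binds the initial value to a registry parameter,
    so a protocol or a sensitivity sample can move it without editing the
    species table.
    """

    name: str
    compartment: str = "cell1"
    initial_value: float = 0.0
    is_constant: bool = False
    is_state_flux: bool = False
    initial_from_param: str | None = None


@dataclass
class Parameter:
    """A named rate constant / quantity with provenance status and bounds."""

    name: str
    value: float
    units: str = ""
    status: str = "assumed"  # known | assumed | fittable
    group: str = "none"      # vegf | hypoxia | none (staged-fit grouping)
    bounds: tuple[float, float] | None = None


@dataclass
class Modifier:
    """Multiplicative regulation of a reaction rate.

    activator: rate *= (1 + ([A]/Ka)**n);  inhibitor: rate /= (1 + ([I]/Ki)**n).
    ``n`` defaults to 1 (first-order modulation) and may be either a fixed
    structural constant or the name of a registry parameter.
    """

    species: str
    role: str  # "activator" | "inhibitor"
    k_param: str
    n: float | str = 1.0


@dataclass
class Reaction:
    """One reaction with a kinetic law drawn from the three families.

    ``law_params`` maps law slots to registry parameter names:

    - mass_action:        {"k"}                rate = k * Π [Ri]**si
    - michaelis_menten:   {"vmax", "km", "substrate"} rate = Vmax·S/(Km+S)
    - hill:               {"vmax", "k", "n", "substrate"} rate = Vmax·Sⁿ/(Kⁿ+Sⁿ)

    MM/Hill accept an optional ``"enzyme"`` species whose concentration
    multiplies the rate (so vmax is a kcat).  The substrate may be a pure
    regulator (not consumed) or also appear among the reactants (consumed).
    """

    name: str
    reactants: list[tuple[str, int]] = field(default_factory=list)
    products: list[tuple[str, int]] = field(default_factory=list)
    law: str = MASS_ACTION
    law_params: dict[str, str] = field(default_factory=dict)
    modifiers: list[Modifier] = field(default_factory=list)
    scope: str = "intra-cell1"  # intra-cell1 | intra-cell2 | trans
    module: str = ""


@dataclass
class ModelDefinition:
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    parameters: dict[str, Parameter] = field(default_factory=dict)
    observables: dict[str, str] = field(default_factory=dict)
    name: str = "model"

    # ---- indexing helpers -------------------------------------------------
    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def parameter_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.parameters)}

    def parameter_vector(self, overrides: dict[str, float] | None = None) -> np.ndarray:
        vals = np.array([p.value for p in self.parameters.values()], float)
        if overrides:
            pidx = self.parameter_index()
            for k, v in overrides.items():
                if k not in pidx:
                    raise UnresolvedParameterError(f"unknown parameter {k!r}")
                vals[pidx[k]] = v
        return vals

    def initial_state(
        self,
        parameter_overrides: dict[str, float] | None = None,
        species_overrides: dict[str, float] | None = None,
    ) -> np.ndarray:
        p = {n: v for n, v in zip(self.parameters, self.parameter_vector(parameter_overrides))}
        y0 = np.empty(len(self.species))
        for i, s in enumerate(self.species):
            y0[i] = p[s.initial_from_param] if s.initial_from_param else s.initial_value
        if species_overrides:
            sidx = self.species_index()
            for k, v in species_overrides.items():
                if k not in sidx:
                    raise ModelValidationError(f"unknown species {k!r}")
                y0[sidx[k]] = v
        return y0

    def copy(self) -> "ModelDefinition":
        return ModelDefinition(
            species=[replace(s) for s in self.species],
            reactions=[
                replace(r, reactants=list(r.reactants), products=list(r.products),
                        law_params=dict(r.law_params), modifiers=[replace(m) for m in r.modifiers])
                for r in self.reactions
            ],
            parameters={n: replace(p) for n, p in self.parameters.items()},
            observables=dict(self.observables),
            name=self.name,
        )

    # ---- validation -------------------------------------------------------
    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for s in self.species:
            if s.compartment not in COMPARTMENTS:
                raise ModelValidationError(f"species {s.name!r}: unknown compartment {s.compartment!r}")
            key = (s.compartment, s.name)
            if key in seen:
                raise ModelValidationError(f"duplicate species name {s.name!r} in {s.compartment!r}")
            seen.add(key)
            if s.initial_from_param is None and s.initial_value < 0:
                raise ModelValidationError(f"species {s.name!r}: negative initial value")
            if s.initial_from_param is not None and s.initial_from_param not in self.parameters:
                raise UnresolvedParameterError(
                    f"species {s.name!r}: initial bound to unknown parameter {s.initial_from_param!r}")
        names = {s.name for s in self.species}
        if len(names) != len(self.species):
            raise ModelValidationError("species names must be globally unique")
        comp_of = {s.name: s.compartment for s in self.species}
        for r in self.reactions:
            self._validate_reaction(r, names, comp_of)
        ident = re.compile(r"(?<![\w.])[A-Za-z_]\w*")
        allowed = names | {"exp", "log", "sqrt", "abs", "minimum", "maximum", "where"}
        for oname, expr in self.observables.items():
            for tok in ident.findall(expr):
                if tok not in allowed:
                    raise ModelValidationError(
                        f"observable {oname!r} references unknown species {tok!r}")

    def _validate_reaction(self, r: Reaction, names: set[str], comp_of: dict[str, str]) -> None:
        if r.law not in LAW_FAMILIES:
            raise ModelValidationError(f"reaction {r.name!r}: unknown law {r.law!r}")
        for sp, st in r.reactants + r.products:
            if sp not in names:
                raise ModelValidationError(f"reaction {r.name!r}: unknown species {sp!r}")
            if not (isinstance(st, (int, np.integer)) and st > 0):
                raise ModelValidationError(f"reaction {r.name!r}: stoichiometry must be a positive integer")
        required = {MASS_ACTION: {"k"}, MICHAELIS_MENTEN: {"vmax", "km", "substrate"},
                    HILL: {"vmax", "k", "n", "substrate"}}[r.law]
        missing = required - set(r.law_params)
        if missing:
            raise ModelValidationError(f"reaction {r.name!r}: missing law params {sorted(missing)}")
        for slot, ref in r.law_params.items():
            if slot in ("substrate", "enzyme"):
                if ref not in names:
                    raise ModelValidationError(f"reaction {r.name!r}: {slot} {ref!r} is not a species")
            elif ref not in self.parameters:
                raise UnresolvedParameterError(f"reaction {r.name!r}: unresolved parameter {ref!r}")
        if r.law == HILL:
            if self.parameters[r.law_params["n"]].value <= 0:
                raise ModelValidationError(f"reaction {r.name!r}: Hill exponent must be > 0")
        for m in r.modifiers:
            if m.species not in names:
                raise ModelValidationError(f"reaction {r.name!r}: modifier species {m.species!r} unknown")
            if m.role not in ("activator", "inhibitor"):
                raise ModelValidationError(f"reaction {r.name!r}: modifier role {m.role!r}")
            if m.k_param not in self.parameters:
                raise UnresolvedParameterError(f"reaction {r.name!r}: modifier parameter {m.k_param!r}")
            if isinstance(m.n, str) and m.n not in self.parameters:
                raise UnresolvedParameterError(f"reaction {r.name!r}: modifier exponent {m.n!r}")
        comps = {comp_of[sp] for sp, _ in r.reactants + r.products}
        for slot in ("substrate", "enzyme"):
            if slot in r.law_params:
                comps.add(comp_of[r.law_params[slot]])
        cellular = comps & {"cell1", "cell2"}
        if r.scope == "trans":
            if cellular != {"cell1", "cell2"}:
                raise ModelValidationError(
                    f"reaction {r.name!r}: trans scope but species span {sorted(cellular)}")
        elif len(cellular) > 1:
            raise ModelValidationError(
                f"reaction {r.name!r}: references both cells but scope is {r.scope!r}")


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

def stoichiometry_matrix(model: ModelDefinition) -> np.ndarray:
    """Integer (species × reactions) matrix N with dy/dt = N @ flux.

    Rows of constant species are zeroed so the identity also holds for
    clamped species (reservoirs, O₂, catalytic co-factors).
    """
    model.validate()
    sidx = model.species_index()
    S = np.zeros((len(model.species), len(model.reactions)), dtype=int)
    for j, r in enumerate(model.reactions):
        for sp, st in r.reactants:
            S[sidx[sp], j] -= st
        for sp, st in r.products:
            S[sidx[sp], j] += st
    for i, s in enumerate(model.species):
        if s.is_constant:
            S[i, :] = 0
    return S


def _term(expr_parts: list[str]) -> str:
    return " * ".join(expr_parts) if expr_parts else "1.0"


def _law_source(r: Reaction, sidx: dict[str, int], pidx: dict[str, int]) -> str:
    lp = r.law_params
    parts: list[str] = []
    if r.law == MASS_ACTION:
        parts.append(f"p[{pidx[lp['k']]}]")
        for sp, st in r.reactants:
            parts.append(f"yc[{sidx[sp]}]" + (f"**{st}" if st != 1 else ""))
    else:
        s = f"yc[{sidx[lp['substrate']]}]"
        parts.append(f"p[{pidx[lp['vmax']]}]")
        if "enzyme" in lp:
            parts.append(f"yc[{sidx[lp['enzyme']]}]")
        if r.law == MICHAELIS_MENTEN:
            parts.append(f"({s} / (p[{pidx[lp['km']]}] + {s}))")
        else:
            n = f"p[{pidx[lp['n']]}]"
            k = f"p[{pidx[lp['k']]}]"
            parts.append(f"({s}**{n} / ({k}**{n} + {s}**{n}))")
        # extra mass-action factors for co-consumed reactants beyond the substrate
        for sp, st in r.reactants:
            if sp != lp["substrate"]:
                parts.append(f"yc[{sidx[sp]}]" + (f"**{st}" if st != 1 else ""))
    src = _term(parts)
    for m in r.modifiers:
        x = f"(yc[{sidx[m.species]}] / p[{pidx[m.k_param]}])"
        if isinstance(m.n, str):
            fac = f"(1.0 + {x}**p[{pidx[m.n]}])"
        elif m.n != 1.0:
            fac = f"(1.0 + {x}**{m.n})"
        else:
            fac = f"(1.0 + {x})"
        src = f"{src} * {fac}" if m.role == "activator" else f"{src} / {fac}"
    return src


class CompiledNetwork:
    """Compiled flux/RHS functions for a validated model.

    Calling the object evaluates ``dy/dt = S @ flux(t, clamp(y), p)``.
    ``n_negative_clamped`` counts RHS calls that saw a meaningfully negative
    state (beyond solver roundoff) and evaluated fluxes on the clamped value.
    """

    def __init__(self, model: ModelDefinition):
        model.validate()
        self.model = model
        self.sidx = model.species_index()
        self.pidx = model.parameter_index()
        self.S = stoichiometry_matrix(model).astype(float)
        lines = ["def _fluxes(t, yc, p, out):"]
        if model.reactions:
            for j, r in enumerate(model.reactions):
                lines.append(f"    out[{j}] = {_law_source(r, self.sidx, self.pidx)}")
        lines.append("    return out")
        ns: dict = {}
        exec("\n".join(lines), ns)  # noqa: S102 - controlled codegen
        self._fluxes = ns["_fluxes"]
        self.source = "\n".join(lines)
        self.n_reactions = len(model.reactions)
        self.n_species = len(model.species)
        self.n_negative_clamped = 0
        self._dep = self._dependency_matrix()
        self.jac_sparsity = (np.abs(self.S) @ self._dep) > 0

    def _dependency_matrix(self) -> np.ndarray:
        dep = np.zeros((self.n_reactions, self.n_species), dtype=int)
        for j, r in enumerate(self.model.reactions):
            for sp, _ in r.reactants:
                dep[j, self.sidx[sp]] = 1
            for slot in ("substrate", "enzyme"):
                if slot in r.law_params:
                    dep[j, self.sidx[r.law_params[slot]]] = 1
            for m in r.modifiers:
                dep[j, self.sidx[m.species]] = 1
        return dep

    def flux(self, t: float, y: np.ndarray, p: np.ndarray) -> np.ndarray:
        yc = np.maximum(y, 0.0)
        return self._fluxes(t, yc, p, np.empty(self.n_reactions))

    def __call__(self, t: float, y: np.ndarray, p: np.ndarray) -> np.ndarray:
        if y.min() < -1e-9:
            self.n_negative_clamped += 1
        return self.S @ self.flux(t, y, p)


def assemble_rhs(model: ModelDefinition) -> CompiledNetwork:
    """Compile the model into a callable RHS ``f(t, y, p) -> dy/dt``.

    Constant species receive a zero derivative; fluxes are evaluated on the
    state clamped at zero so transient solver undershoots cannot produce
    spurious negative-concentration kinetics.
    """
    return CompiledNetwork(model)
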